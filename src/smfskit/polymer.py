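"""Closed-form polymer elasticity and kinetics used throughout the toolkit.

Experimental-side quantities are expressed in nm, pN and s; the
coarse-grained simulation side works in Å, ε and τ.  The only bridges
between the two unit systems are :func:`sim_force_to_pN` and
:func:`cg_time_unit`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PhysicalConstants",
    "WLCParams",
    "BellEvansParams",
    "wlc_force",
    "wlc_inverse_extension",
    "loading_rate",
    "bell_evans_force",
    "thermal_force_rms",
    "cg_time_unit",
    "sim_force_to_pN",
]

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants shared by the experimental and simulation sides.

    Attributes
    ----------
    kBT_pNnm:
        Thermal energy at room temperature, in pN·nm.
    eps_kcal_mol:
        Uniform native-contact energy ε of the coarse-grained model, in
        kcal/mol (0.6 kcal/mol = 2510.4 J/mol, chosen equal to kBT).
    aa_mass_kg:
        Mean amino-acid mass in kg.
    sigma_A:
        Spacing between successive Cα beads, in Å.
    """

    kBT_pNnm: float = 4.1
    eps_kcal_mol: float = 0.6
    aa_mass_kg: float = 4.6e-26
    sigma_A: float = 3.6

    def __post_init__(self) -> None:
        for name in ("kBT_pNnm", "eps_kcal_mol", "aa_mass_kg", "sigma_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def eps_J(self) -> float:
        """Contact energy ε per particle, in joules."""
        return self.eps_kcal_mol * 4184.0 / AVOGADRO


@dataclass(frozen=True)
class WLCParams:
    """Worm-like-chain parameters: contour length Lc and persistence length p (nm)."""

    Lc_nm: float
    p_nm: float = 0.36

    def __post_init__(self) -> None:
        if self.Lc_nm <= 0:
            raise ValueError("Lc_nm must be > 0")
        if self.p_nm <= 0:
            raise ValueError("p_nm must be > 0")


@dataclass(frozen=True)
class BellEvansParams:
    """Bell–Evans kinetic parameters.

    xu_nm is the distance from the folded minimum to the unfolding barrier
    along the pulling coordinate; ku_per_s is the unfolding rate at zero
    force.
    """

    xu_nm: float
    ku_per_s: float

    def __post_init__(self) -> None:
        if self.xu_nm <= 0:
            raise ValueError("xu_nm must be > 0")
        if self.ku_per_s <= 0:
            raise ValueError("ku_per_s must be > 0")


_DEFAULT_CONSTS = PhysicalConstants()


def wlc_force(
    x: float,
    params: WLCParams,
    consts: PhysicalConstants = _DEFAULT_CONSTS,
) -> float:
    """Interpolated worm-like-chain force (pN) at extension ``x`` (nm).

    F(x) = (kBT/p) · [ 1/(4(1 − x/Lc)²) − 1/4 + x/Lc ]

    Strictly increasing on [0, Lc) and divergent as x → Lc.
    """
    if x < 0 or x >= params.Lc_nm:
        raise ValueError(f"extension {x} outside the WLC domain [0, Lc={params.Lc_nm})")
    t = x / params.Lc_nm
    return (consts.kBT_pNnm / params.p_nm) * (0.25 / (1.0 - t) ** 2 - 0.25 + t)


def wlc_inverse_extension(
    F: float,
    params: WLCParams,
    consts: PhysicalConstants = _DEFAULT_CONSTS,
    rtol: float = 1e-9,
) -> float:
    """Extension x (nm) at which the WLC force equals ``F`` (pN).

    The WLC force is strictly monotone on [0, Lc), so the root is unique;
    it is bracketed by bisection and polished with Newton steps.
    """
    if F < 0:
        raise ValueError("force must be non-negative")
    if F == 0.0:
        return 0.0
    Lc, p = params.Lc_nm, params.p_nm
    scale = consts.kBT_pNnm / p

    def f(x: float) -> float:
        t = x / Lc
        return scale * (0.25 / (1.0 - t) ** 2 - 0.25 + t) - F

    def fprime(x: float) -> float:
        t = x / Lc
        return scale * (0.5 / (1.0 - t) ** 3 + 1.0) / Lc

    lo, hi = 0.0, Lc * (1.0 - 1e-15)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-3 * Lc:
            break
    x = 0.5 * (lo + hi)
    for _ in range(200):
        fx = f(x)
        if fx < 0.0:
            lo = x
        else:
            hi = x
        x_new = x - fx / fprime(x)
        if not (lo < x_new < hi):
            x_new = 0.5 * (lo + hi)  # fall back to bisection inside the bracket
        if abs(x_new - x) <= rtol * max(abs(x_new), 1e-30) and abs(fx) <= 1e-9 * max(
            F, 1e-30
        ):
            return x_new
        x = x_new
    return x


def loading_rate(
    v: float,
    x: float,
    params: WLCParams,
    consts: PhysicalConstants = _DEFAULT_CONSTS,
) -> float:
    """Loading rate (pN/s): pulling speed times the WLC stiffness dF/dx.

    lr = v · (kBT/p) · [ (1/(2Lc))(1 − x/Lc)⁻³ + 1/Lc ]
    """
    if x < 0 or x >= params.Lc_nm:
        raise ValueError(f"extension {x} outside the WLC domain [0, Lc={params.Lc_nm})")
    Lc = params.Lc_nm
    t = x / Lc
    stiffness = (consts.kBT_pNnm / params.p_nm) * (0.5 / Lc / (1.0 - t) ** 3 + 1.0 / Lc)
    return v * stiffness


def bell_evans_force(
    lr: float,
    params: BellEvansParams,
    consts: PhysicalConstants = _DEFAULT_CONSTS,
) -> float:
    """Most probable rupture force (pN) at loading rate ``lr`` (pN/s).

    Fp = (kBT/xu) · ln( xu·lr / (kBT·ku) )

    The force grows linearly in ln(lr) with slope kBT/xu.
    """
    if lr <= 0:
        raise ValueError("loading rate must be > 0")
    arg = params.xu_nm * lr / (consts.kBT_pNnm * params.ku_per_s)
    if arg <= 0:
        raise ValueError("logarithm argument must be positive")
    return (consts.kBT_pNnm / params.xu_nm) * math.log(arg)


def thermal_force_rms(
    kc: float,
    consts: PhysicalConstants = _DEFAULT_CONSTS,
) -> float:
    """RMS force noise (pN) of a cantilever of stiffness ``kc`` (N/m).

    ΔF_rms = sqrt(kc · kBT); kc is converted from N/m to pN/nm (×1000).
    This sets the natural bin width of rupture-force histograms.
    """
    if kc <= 0:
        raise ValueError("cantilever stiffness must be > 0")
    kc_pN_nm = kc * 1000.0
    return math.sqrt(kc_pN_nm * consts.kBT_pNnm)


def cg_time_unit(consts: PhysicalConstants = _DEFAULT_CONSTS) -> float:
    """Coarse-grained time unit τ = σ·sqrt(m/ε), in seconds (~1 ps)."""
    sigma_m = consts.sigma_A * 1e-10
    return sigma_m * math.sqrt(consts.aa_mass_kg / consts.eps_J)


def sim_force_to_pN(f: float, consts: PhysicalConstants = _DEFAULT_CONSTS) -> float:
    """Convert a simulation force in ε/Å to pN (1 ε/Å ≈ 41.7 pN)."""
    return f * consts.eps_J / 1e-10 * 1e12
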