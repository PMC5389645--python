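"""Constant-velocity pulling simulations of the coarse-grained Go model.

The chain is tethered by two harmonic springs: one holds the anchor
residue (C-terminal by default) at its native position; the other — the
pulling spring — is attached to the pull residue and its base moves at
constant velocity v_p along the native anchor→pull axis.  The recorded
pulling force is the extension of the pulling spring along that axis
times its force constant Kp.  Dynamics are BAOAB Langevin in reduced
units (Å, ε, τ, m = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _kernels
from .gomodel import CGStructure, GoHamiltonian
from .polymer import PhysicalConstants, sim_force_to_pN
from .traces import DetectionParams, ForceExtensionTrace, detect_peaks

__all__ = [
    "PullingProtocol",
    "LangevinParams",
    "SimTrace",
    "SimEvent",
    "run_pulling",
    "detect_sim_events",
    "unfolding_order",
    "sim_trace_to_force_extension",
    "write_sim_trace",
]


@dataclass(frozen=True)
class PullingProtocol:
    """Dual-spring constant-velocity protocol.

    anchor_residue / pull_residue are 1-based bead positions; by default
    the C-terminal bead is held fixed and the N-terminal bead is pulled.
    v_p is the spring-base velocity in Å/τ.
    """

    anchor_residue: int = -1  # -1 = C-terminal
    pull_residue: int = 1
    Kp: float = 1.0
    K_anchor: float = 1.0
    v_p: float = 5e-3

    def __post_init__(self) -> None:
        if self.Kp <= 0 or self.K_anchor <= 0 or self.v_p < 0:
            raise ValueError("spring constants must be > 0 and v_p >= 0")

    def resolve(self, n: int) -> tuple[int, int]:
        """0-based (anchor, pull) bead indices for an n-bead chain."""
        a = n - 1 if self.anchor_residue == -1 else self.anchor_residue - 1
        p = self.pull_residue - 1
        if not (0 <= a < n and 0 <= p < n) or a == p:
            raise ValueError("invalid anchor/pull residues")
        return a, p


@dataclass(frozen=True)
class LangevinParams:
    """Thermostat and integration settings (reduced units)."""

    kT_eps: float = 1.0
    gamma_per_tau: float = 1.0
    dt_tau: float = 0.005
    n_steps: int = 1_000_000
    n_equil_steps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_tau > 0.01:
            raise ValueError("time step must be <= 0.01 τ")
        if self.kT_eps < 0 or self.gamma_per_tau < 0:
            raise ValueError("kT and gamma must be non-negative")


@dataclass
class SimTrace:
    """Recorded pulling run (reduced units)."""

    time_tau: np.ndarray
    pull_force_eps_A: np.ndarray
    chain_extension_A: np.ndarray  # anchor-to-pull bead distance
    pulled_distance_A: np.ndarray  # spring-base displacement v_p · t
    domain_extension_A: dict[str, np.ndarray]
    potential_eps: np.ndarray
    kinetic_eps: np.ndarray
    v_p: float
    seed: int

    def __post_init__(self) -> None:
        n = self.time_tau.size
        for arr in (self.pull_force_eps_A, self.chain_extension_A, self.pulled_distance_A):
            if arr.size != n:
                raise ValueError("series length mismatch")
        if not np.all(np.isfinite(self.pull_force_eps_A)):
            raise ValueError("non-finite forces in trace")


def run_pulling(
    structure: CGStructure,
    hamiltonian: GoHamiltonian,
    protocol: PullingProtocol = PullingProtocol(),
    langevin: LangevinParams = LangevinParams(),
    record_every: int = 200,
) -> SimTrace:
    """Equilibrate with static springs, then pull at constant velocity.

    Reproducible for a fixed seed (bit-identical recorded series).  Raises
    on numeric blow-up, naming the step at which it occurred.
    """
    n = structure.n_residues
    a_idx, p_idx = protocol.resolve(n)
    x0 = structure.coords_A
    axis = x0[p_idx] - x0[a_idx]
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("anchor and pull positions coincide")
    axis = axis / norm

    coords = np.ascontiguousarray(x0, dtype=np.float64).copy()
    rng = np.random.default_rng(langevin.seed)
    if langevin.kT_eps > 0:
        vels = rng.normal(0.0, np.sqrt(langevin.kT_eps), size=(n, 3))
    else:
        vels = np.zeros((n, 3))

    ham_args = (
        hamiltonian.bond_idx, hamiltonian.bond_b0, hamiltonian.k_bond,
        hamiltonian.angle_idx, hamiltonian.angle_theta0, hamiltonian.k_angle,
        hamiltonian.dihedral_idx, hamiltonian.dihedral_phi0,
        hamiltonian.k_dihedral_1, hamiltonian.k_dihedral_3,
        hamiltonian.contact_idx, hamiltonian.contact_r0, hamiltonian.contact_eps,
        hamiltonian.repulsion_idx, hamiltonian.r_repulsive_A,
    )
    anchor_pos = x0[a_idx].copy()
    pull_base0 = x0[p_idx].copy()

    # equilibration: both springs static (v_p = 0)
    if langevin.n_equil_steps > 0:
        out = _kernels.run_langevin(
            coords, vels, *ham_args,
            a_idx, p_idx, anchor_pos, pull_base0, axis,
            protocol.K_anchor, protocol.Kp, 0.0,
            langevin.dt_tau, langevin.gamma_per_tau, langevin.kT_eps,
            langevin.n_equil_steps, max(langevin.n_equil_steps, 1),
            int(langevin.seed) % 2**31,
        )
        if out[5] != 0:
            raise RuntimeError(f"numeric blow-up during equilibration at step {out[5]}")

    times, forces, pot, kin, snaps, status = _kernels.run_langevin(
        coords, vels, *ham_args,
        a_idx, p_idx, anchor_pos, pull_base0, axis,
        protocol.K_anchor, protocol.Kp, protocol.v_p,
        langevin.dt_tau, langevin.gamma_per_tau, langevin.kT_eps,
        langevin.n_steps, record_every,
        (int(langevin.seed) + 1) % 2**31,
    )
    if status != 0:
        raise RuntimeError(f"numeric blow-up during pulling at step {status}")

    chain_ext = np.linalg.norm(snaps[:, p_idx, :] - snaps[:, a_idx, :], axis=1)
    domain_ext: dict[str, np.ndarray] = {}
    for name in structure.domain_ranges:
        idx = np.nonzero(structure.domain_mask(name))[0]
        domain_ext[name] = np.linalg.norm(
            snaps[:, idx[-1], :] - snaps[:, idx[0], :], axis=1
        )
    return SimTrace(
        time_tau=times,
        pull_force_eps_A=forces,
        chain_extension_A=chain_ext,
        pulled_distance_A=protocol.v_p * times,
        domain_extension_A=domain_ext,
        potential_eps=pot,
        kinetic_eps=kin,
        v_p=protocol.v_p,
        seed=langevin.seed,
    )


@dataclass(frozen=True)
class SimEvent:
    """One rupture in a simulated pulling run."""

    time_tau: float
    force_eps_A: float
    force_pN: float
    domain: str | None
    domain_extension_change_A: float


def sim_trace_to_force_extension(
    sim: SimTrace,
    consts: PhysicalConstants = PhysicalConstants(),
    trace_id: str = "sim",
) -> ForceExtensionTrace:
    """Convert a pulling run to experimental axes (nm, pN).

    The extension axis is the pulled distance v_p·t (strictly increasing);
    forces convert through the ε/Å → pN bridge.  The nominal pulling speed
    in nm/s follows from v_p and the coarse-grained time unit.
    """
    from .polymer import cg_time_unit

    ext_nm = sim.pulled_distance_A * 0.1
    force_pN = np.array([sim_force_to_pN(f, consts) for f in sim.pull_force_eps_A])
    v_nm_s = sim.v_p * 0.1 / cg_time_unit(consts)
    return ForceExtensionTrace(
        extension_nm=ext_nm,
        force_pN=force_pN,
        pulling_speed_nm_s=v_nm_s,
        trace_id=trace_id,
        source="simulation",
    )


def detect_sim_events(
    sim: SimTrace,
    params: DetectionParams | None = None,
    consts: PhysicalConstants = PhysicalConstants(),
) -> list[SimEvent]:
    """Force peaks of a pulling run, attributed to domains.

    The rupture peaks are found with the same detector used for
    experimental traces after unit conversion.  Each peak is attributed to
    the domain whose end-to-end extension increases most across the force
    drop that follows the peak; without domain definitions the attribution
    is skipped.
    """
    if params is None:
        # smooth over ~2 Å of pulled distance: long enough to average the
        # thermal fluctuation of the pulling spring, short against ruptures
        params = DetectionParams(smooth_window_nm=0.2, min_prominence_pN=30.0,
                                 min_drop_pN=20.0)
    trace = sim_trace_to_force_extension(sim, consts)
    peaks = detect_peaks(trace, params)
    events: list[SimEvent] = []
    force = trace.force_pN
    n = force.size
    for k, pk in enumerate(peaks):
        nxt = peaks[k + 1] if k + 1 < len(peaks) else n
        trough = pk + int(np.argmin(force[pk:nxt])) if nxt > pk else pk
        domain = None
        best_gain = 0.0
        for name, ext in sim.domain_extension_A.items():
            gain = float(ext[trough] - ext[pk])
            if gain > best_gain:
                best_gain = gain
                domain = name
        events.append(
            SimEvent(
                time_tau=float(sim.time_tau[pk]),
                force_eps_A=float(sim.pull_force_eps_A[pk]),
                force_pN=float(force[pk]),
                domain=domain,
                domain_extension_change_A=best_gain,
            )
        )
    return events


def unfolding_order(events: Sequence[SimEvent]) -> list[str]:
    """Domains ordered by the time of their first attributed rupture."""
    first_seen: dict[str, float] = {}
    for ev in sorted(events, key=lambda e: e.time_tau):
        if ev.domain is not None and ev.domain not in first_seen:
            first_seen[ev.domain] = ev.time_tau
    return sorted(first_seen, key=first_seen.get)


def write_sim_trace(sim: SimTrace, path: str | Path) -> None:
    """Write a pulling run as tabular text (reduced units)."""
    names = sorted(sim.domain_extension_A)
    with Path(path).open("w") as fh:
        fh.write(f"#v_p_A_per_tau={sim.v_p!r}\n#seed={sim.seed}\n")
        cols = ["time_tau", "force_eps_A", "chain_ext_A"] + [f"ext_{n}_A" for n in names]
        fh.write("#" + "\t".join(cols) + "\n")
        for k in range(sim.time_tau.size):
            row = [sim.time_tau[k], sim.pull_force_eps_A[k], sim.chain_extension_A[k]]
            row += [sim.domain_extension_A[n][k] for n in names]
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")
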