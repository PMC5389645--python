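"""Ensemble statistics over pooled unfolding events.

Events from many traces are pooled into the (ΔLc, F) phase space, binned
on a 10 pN × 5 nm grid, and the marginal histograms are fitted with a sum
of two Gaussians to extract the most probable rupture force Fp and
contour-length increment ΔLc_p of each population.  Across pulling speeds
the (loading rate, Fp) points form a dynamic force spectrum fitted with
the Bell–Evans model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .polymer import BellEvansParams, PhysicalConstants
from .traces import TraceAnalysis

__all__ = [
    "EventEnsemble",
    "PhaseSpaceGrid",
    "TwoGaussianFit",
    "ForceSpectrum",
    "pool_events",
    "build_phase_space",
    "histogram_counts",
    "fit_two_gaussians",
    "most_probable",
    "dynamic_force_spectrum",
]

FORCE_BIN_PN = 10.0  # thermal-noise-limited force resolution
DLC_BIN_NM = 5.0  # smallest measurable contour-length feature


@dataclass
class EventEnsemble:
    """Pooled (ΔLc, F) pairs for one experimental condition.

    Each ΔLc interval is paired with the force of the event that terminates
    it (the later of the two sequential peaks).
    """

    pairs: list[tuple[float, float]]
    condition_label: str = "apo"
    pulling_speed_nm_s: float = 200.0
    loading_rates_pN_s: list[float] = field(default_factory=list)
    event_forces_pN: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for dlc, f in self.pairs:
            if dlc <= 0 or f <= 0:
                raise ValueError("all ΔLc and F values must be positive")
        if not self.event_forces_pN:
            self.event_forces_pN = [f for _, f in self.pairs]

    @property
    def delta_Lc_nm(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs])

    @property
    def force_pN(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs])


def pool_events(
    analyses: Iterable[TraceAnalysis],
    condition_label: str = "apo",
    pulling_speed_nm_s: float = 200.0,
    accepted_only: bool = True,
) -> EventEnsemble:
    """Pool per-trace analyses into one (ΔLc, F) ensemble.

    Within a trace with events e_1..e_n, interval i contributes the pair
    (Lc_{i+1} − Lc_i, rupture force of e_{i+1}); negative increments (fit
    artifacts) are dropped.  ``event_forces_pN`` collects the rupture
    forces of all retained events — the sample the force histograms use.
    """
    pairs: list[tuple[float, float]] = []
    lrs: list[float] = []
    event_forces: list[float] = []
    for ana in analyses:
        if accepted_only and not ana.accepted:
            continue
        for ev in ana.events:
            f = ev.rupture_force_pN or ev.peak_force_pN
            if f > 0:
                event_forces.append(f)
                lrs.append(ev.loading_rate_pN_s)
        for i, dlc in enumerate(ana.delta_Lc_nm):
            ev = ana.events[i + 1]
            f_term = ev.rupture_force_pN or ev.peak_force_pN
            if dlc > 0 and f_term > 0:
                pairs.append((dlc, f_term))
    return EventEnsemble(
        pairs=pairs,
        condition_label=condition_label,
        pulling_speed_nm_s=pulling_speed_nm_s,
        loading_rates_pN_s=lrs,
        event_forces_pN=event_forces,
    )


def pool_events_frame(
    frame,
    condition_label: str = "apo",
    pulling_speed_nm_s: float = 200.0,
    accepted_only: bool = True,
) -> EventEnsemble:
    """Pool a tabular events file (one row per event) into an ensemble.

    Rows are grouped by trace_id and ordered by event_index; each ΔLc
    interval is paired with the force of the terminating event, as in
    :func:`pool_events`.
    """
    pairs: list[tuple[float, float]] = []
    lrs: list[float] = []
    event_forces: list[float] = []
    if accepted_only and "accepted" in frame.columns:
        frame = frame[frame["accepted"]]
    force_col = "rupture_force_pN" if "rupture_force_pN" in frame.columns else "peak_force_pN"
    for _, grp in frame.groupby("trace_id", sort=True):
        grp = grp.sort_values("event_index")
        lcs = grp["Lc_nm"].to_numpy()
        forces = grp[force_col].to_numpy()
        rates = grp["loading_rate_pN_s"].to_numpy()
        event_forces.extend(float(f) for f in forces if f > 0)
        lrs.extend(float(r) for f, r in zip(forces, rates) if f > 0)
        for i in range(len(lcs) - 1):
            dlc = lcs[i + 1] - lcs[i]
            if dlc > 0 and forces[i + 1] > 0:
                pairs.append((float(dlc), float(forces[i + 1])))
    return EventEnsemble(
        pairs=pairs,
        condition_label=condition_label,
        pulling_speed_nm_s=pulling_speed_nm_s,
        loading_rates_pN_s=lrs,
        event_forces_pN=event_forces,
    )


@dataclass
class PhaseSpaceGrid:
    """2-D event counts over (ΔLc, F) with half-open bins."""

    dlc_bin_nm: float
    force_bin_pN: float
    dlc_origin_nm: float
    force_origin_pN: float
    counts: np.ndarray  # shape (n_dlc_bins, n_force_bins)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_table(self) -> list[tuple[float, float, int]]:
        """Rows (dlc_bin_start, force_bin_start, count), nonzero cells only."""
        rows = []
        for i in range(self.counts.shape[0]):
            for j in range(self.counts.shape[1]):
                c = int(self.counts[i, j])
                if c:
                    rows.append(
                        (
                            self.dlc_origin_nm + i * self.dlc_bin_nm,
                            self.force_origin_pN + j * self.force_bin_pN,
                            c,
                        )
                    )
        return rows


def build_phase_space(
    ensemble: EventEnsemble,
    force_bin_pN: float = FORCE_BIN_PN,
    dlc_bin_nm: float = DLC_BIN_NM,
    dlc_origin_nm: float = 0.0,
    force_origin_pN: float = 0.0,
) -> PhaseSpaceGrid:
    """Bin the (ΔLc, F) pairs on a half-open grid; counts are conserved.

    A value exactly on a bin edge belongs to the higher bin.
    """
    if not ensemble.pairs:
        raise ValueError("cannot bin an empty ensemble")
    if force_bin_pN <= 0 or dlc_bin_nm <= 0:
        raise ValueError("bin widths must be positive")
    dlc = ensemble.delta_Lc_nm
    force = ensemble.force_pN
    i = np.floor((dlc - dlc_origin_nm) / dlc_bin_nm).astype(int)
    j = np.floor((force - force_origin_pN) / force_bin_pN).astype(int)
    if (i < 0).any() or (j < 0).any():
        raise ValueError("pairs below the grid origin")
    counts = np.zeros((i.max() + 1, j.max() + 1), dtype=int)
    np.add.at(counts, (i, j), 1)
    return PhaseSpaceGrid(dlc_bin_nm, force_bin_pN, dlc_origin_nm, force_origin_pN, counts)


def histogram_counts(
    values: np.ndarray | Sequence[float],
    bin_width: float,
    origin: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Half-open histogram; returns (bin centers, counts) up to the data max."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to histogram")
    idx = np.floor((values - origin) / bin_width).astype(int)
    if (idx < 0).any():
        raise ValueError("values below the histogram origin")
    counts = np.bincount(idx)
    centers = origin + (np.arange(counts.size) + 0.5) * bin_width
    return centers, counts.astype(float)


@dataclass
class TwoGaussianFit:
    """Sum-of-two-Gaussians fit to a binned histogram.

    ``separation_p_value`` is a covariance-based two-sided t-test of
    c2 − c1 ≠ 0; ``single_population`` flags a degenerate fit in which the
    two centers collapsed within one bin.
    """

    centers: tuple[float, float]
    widths: tuple[float, float]
    amplitudes: tuple[float, float]
    separation_p_value: float
    fit_rmse: float
    single_population: bool = False

    def __post_init__(self) -> None:
        if self.centers[0] > self.centers[1]:
            raise ValueError("centers must be ordered c1 <= c2")


def _mixture(x: np.ndarray, a1, c1, s1, a2, c2, s2) -> np.ndarray:
    return a1 * np.exp(-0.5 * ((x - c1) / s1) ** 2) + a2 * np.exp(
        -0.5 * ((x - c2) / s2) ** 2
    )


def fit_two_gaussians(
    bin_centers: np.ndarray | Sequence[float],
    counts: np.ndarray | Sequence[float],
) -> TwoGaussianFit:
    """Nonlinear least-squares two-Gaussian fit to binned counts.

    Counts are Poisson, so bins are weighted by sigma_i = sqrt(y_i + 1);
    five deterministic initializations are tried (weighted 25th/75th
    percentile centers, then ±1-bin perturbations of each center) and the
    converged fit with the lowest weighted RMSE wins.  Requires ≥ 6
    nonzero bins.
    """
    x = np.asarray(bin_centers, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.shape != y.shape:
        raise ValueError("bin centers and counts must have equal length")
    if int((y > 0).sum()) < 6:
        raise ValueError("need at least 6 nonzero bins for a two-Gaussian fit")
    w = np.diff(np.sort(x)).min() if x.size > 1 else 1.0

    total = y.sum()
    order = np.argsort(x)
    cum = np.cumsum(y[order]) / total
    q25 = float(x[order][np.searchsorted(cum, 0.25)])
    q75 = float(x[order][np.searchsorted(cum, 0.75)])
    mean = float((x * y).sum() / total)
    sd = float(np.sqrt(((x - mean) ** 2 * y).sum() / total))
    s0 = max(sd / 2.0, w / 2.0)
    a0 = float(y.max())

    starts = [
        (q25, q75),
        (q25 - w, q75),
        (q25 + w, q75),
        (q25, q75 - w),
        (q25, q75 + w),
    ]

    best = None
    for c1_0, c2_0 in starts:
        p0 = [a0, c1_0, s0, a0, c2_0, s0]
        lo = [0.0, x.min() - 2 * w, w / 10.0, 0.0, x.min() - 2 * w, w / 10.0]
        span = float(np.ptp(x)) + w
        hi = [np.inf, x.max() + 2 * w, span, np.inf, x.max() + 2 * w, span]
        try:
            popt, pcov = optimize.curve_fit(
                _mixture, x, y, p0=p0, bounds=(lo, hi), maxfev=20000,
                sigma=np.sqrt(y + 1.0), absolute_sigma=True,
            )
        except (RuntimeError, ValueError):
            continue
        rmse = float(
            np.sqrt(np.mean(((_mixture(x, *popt) - y) / np.sqrt(y + 1.0)) ** 2))
        )
        if best is None or rmse < best[2]:
            best = (popt, pcov, rmse)
    if best is None:
        raise RuntimeError("two-Gaussian fit failed to converge from all starts")
    popt, pcov, rmse = best

    a1, c1, s1, a2, c2, s2 = popt
    comps = [(a1, c1, abs(s1), 1), (a2, c2, abs(s2), 4)]
    comps.sort(key=lambda t: t[1])
    (A1, C1, S1, k1), (A2, C2, S2, k2) = comps

    # t-test on center separation using the fit covariance
    var = pcov[k1, k1] + pcov[k2, k2] - 2.0 * pcov[k1, k2]
    dof = max(x.size - 6, 1)
    if var <= 0 or not np.isfinite(var):
        p_value = 1.0
    else:
        t_stat = (C2 - C1) / np.sqrt(var)
        p_value = 2.0 * stats.t.sf(abs(t_stat), dof)

    return TwoGaussianFit(
        centers=(C1, C2),
        widths=(S1, S2),
        amplitudes=(A1, A2),
        separation_p_value=float(p_value),
        fit_rmse=rmse,
        single_population=bool(abs(C2 - C1) <= w),
    )


def most_probable(fit: TwoGaussianFit) -> tuple[float, float]:
    """The two fitted population centers (Fp or ΔLc_p), low first."""
    return fit.centers


@dataclass
class ForceSpectrum:
    """Dynamic force spectrum: (mean loading rate, Fp) per pulling speed."""

    points: list[tuple[float, float]]
    params: BellEvansParams


def dynamic_force_spectrum(
    entries: Sequence[tuple[float, TwoGaussianFit]],
    family: Literal["low", "high"] = "low",
    consts: PhysicalConstants = PhysicalConstants(),
) -> ForceSpectrum:
    """Fit the Bell–Evans model to per-speed (loading rate, Fp) points.

    ``entries`` pairs each speed's mean loading rate (pN/s) with the
    two-Gaussian fit of its force histogram; ``family`` selects the lower-
    or higher-force center as Fp.  Returns the fitted barrier distance xu
    (nm) and zero-force rate ku (1/s).
    """
    if len(entries) < 2:
        raise ValueError("need ensembles at >= 2 pulling speeds")
    lrs = np.array([e[0] for e in entries], dtype=float)
    if np.unique(lrs).size < 2:
        raise ValueError("loading rates carry no slope information")
    idx = 0 if family == "low" else 1
    fps = np.array([e[1].centers[idx] for e in entries], dtype=float)
    kBT = consts.kBT_pNnm

    def model(lr, xu, log_ku):
        return (kBT / xu) * (np.log(xu * lr / kBT) - log_ku)

    slope = np.polyfit(np.log(lrs), fps, 1)[0]
    xu0 = float(np.clip(kBT / max(slope, 1e-3), 1e-3, 100.0))
    popt, _ = optimize.curve_fit(
        model, lrs, fps, p0=[xu0, 0.0], bounds=([1e-6, -60.0], [1e3, 60.0]), maxfev=20000
    )
    xu, log_ku = popt
    params = BellEvansParams(xu_nm=float(xu), ku_per_s=float(np.exp(log_ku)))
    return ForceSpectrum(points=[(float(l), float(f)) for l, f in zip(lrs, fps)], params=params)
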