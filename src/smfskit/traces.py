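"""Force–extension trace analysis.

Turns one raw AFM pulling cycle into a list of unfolding events: peak
detection on the sawtooth, a worm-like-chain fit to the rising phase of
each peak (persistence length fixed, contour length free), contour-length
increments ΔLc between sequential peaks, and per-event loading rates.

The first peak of a trace (usually tip–surface adhesion) and the last
(detachment of the molecule from tip or surface) are excluded; a trace is
accepted only if at least ``min_events`` clear sequential unfolding events
remain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .polymer import PhysicalConstants, WLCParams, loading_rate, wlc_force

__all__ = [
    "ForceExtensionTrace",
    "DetectionParams",
    "UnfoldingEvent",
    "TraceAnalysis",
    "detect_peaks",
    "select_events",
    "fit_wlc_segment",
    "compute_event_metrics",
    "analyze_trace",
    "read_trace",
    "write_trace",
    "write_events",
    "read_events",
]

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "trace_id",
    "event_index",
    "peak_force_pN",
    "rupture_force_pN",
    "peak_extension_nm",
    "Lc_nm",
    "loading_rate_pN_s",
    "fit_rmse_pN",
    "accepted",
]


@dataclass
class ForceExtensionTrace:
    """One pulling cycle: tip–surface extension (nm) vs measured force (pN)."""

    extension_nm: np.ndarray
    force_pN: np.ndarray
    pulling_speed_nm_s: float = 200.0
    cantilever_k_N_m: float = 0.025
    trace_id: str = "trace"
    source: Literal["experiment", "synthetic", "simulation"] = "experiment"

    def __post_init__(self) -> None:
        self.extension_nm = np.asarray(self.extension_nm, dtype=float)
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        if self.extension_nm.shape != self.force_pN.shape:
            raise ValueError("extension and force series must have equal length")
        if self.extension_nm.size < 10:
            raise ValueError("trace must contain at least 10 samples")
        if not np.all(np.diff(self.extension_nm) > 0):
            raise ValueError("extension must be strictly increasing")
        if self.pulling_speed_nm_s <= 0:
            raise ValueError("pulling speed must be > 0")

    @property
    def n_samples(self) -> int:
        return self.extension_nm.size


@dataclass(frozen=True)
class DetectionParams:
    """Tunable thresholds of the peak detector and WLC fit windows."""

    smooth_window_nm: float = 1.0
    min_prominence_pN: float = 20.0
    min_drop_pN: float = 15.0
    engage_threshold_pN: float = 10.0
    min_events: int = 2
    min_feature_nm: float = 5.0  # smallest resolvable contour-length change

    def __post_init__(self) -> None:
        for name in (
            "smooth_window_nm",
            "min_prominence_pN",
            "min_drop_pN",
            "engage_threshold_pN",
            "min_events",
            "min_feature_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class UnfoldingEvent:
    """One rupture: peak force, fitted contour length, loading rate.

    ``peak_force_pN`` is the raw force at the detected peak sample;
    ``rupture_force_pN`` is the sub-sample estimate from the fitted WLC
    evaluated midway between the last sample on the branch and the first
    after the drop, which removes the half-sample discretization bias of
    the raw readout.
    """

    peak_force_pN: float
    peak_extension_nm: float
    Lc_nm: float
    p_nm: float
    loading_rate_pN_s: float
    fit_rmse_pN: float
    index_range: tuple[int, int]
    rupture_force_pN: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.peak_extension_nm < self.Lc_nm):
            raise ValueError("peak extension must lie strictly inside (0, Lc)")
        if self.peak_force_pN <= 0:
            raise ValueError("peak force must be > 0")


@dataclass
class TraceAnalysis:
    """Analysis result for one trace: retained events, ΔLc list, accept flag."""

    trace: ForceExtensionTrace
    events: list[UnfoldingEvent]
    delta_Lc_nm: list[float] = field(default_factory=list)
    accepted: bool = False


def _noise_sd(force: np.ndarray) -> float:
    """Robust per-sample noise SD from successive differences."""
    d = np.diff(force)
    return float(np.median(np.abs(d)) / 0.6745 / np.sqrt(2.0))


def _smooth(
    force: np.ndarray,
    extension: np.ndarray,
    window_nm: float,
    adapt_to_pN: float | None = None,
) -> np.ndarray:
    """Boxcar smoothing over at least ``window_nm`` of extension.

    With ``adapt_to_pN`` set, the window widens until the residual noise of
    the smoothed trace sits about five standard deviations below that force
    scale, so that the peak detector's thresholds stay meaningful at any
    instrument noise level; the configured width acts as the minimum.
    """
    dx = float(np.median(np.diff(extension)))
    n_win = max(1, int(round(window_nm / dx)))
    if adapt_to_pN is not None:
        sd = _noise_sd(force)
        n_needed = int(np.ceil((5.0 * sd / adapt_to_pN) ** 2))
        n_win = max(n_win, n_needed)
    if n_win % 2 == 0:
        n_win += 1
    if n_win >= force.size:
        raise ValueError("trace shorter than the smoothing window")
    if n_win == 1:
        return force.astype(float)
    kernel = np.ones(n_win) / n_win
    padded = np.pad(force, n_win // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def detect_peaks(trace: ForceExtensionTrace, params: DetectionParams) -> list[int]:
    """Candidate rupture peaks, as indices into the raw series.

    Local maxima of the boxcar-smoothed force with prominence at least
    ``min_prominence_pN`` are kept only if the smoothed force subsequently
    drops by at least ``min_drop_pN`` before the next peak (or trace end).
    Peak positions are refined to the raw-force maximum near the smoothed
    peak.  Deterministic for a fixed input.
    """
    smoothed = _smooth(
        trace.force_pN,
        trace.extension_nm,
        params.smooth_window_nm,
        adapt_to_pN=params.min_prominence_pN,
    )
    # hysteresis segmentation of the sawtooth: an excursion opens when the
    # smoothed force has risen min_prominence above the running trough (and
    # above the zero-force baseline by the same amount); its running
    # maximum is emitted as the peak once the force has fallen min_drop
    peaks: list[int] = []
    # traces are baseline-corrected: the pre-engagement force is zero, so a
    # trace that starts mid-rise still measures its first rise from zero
    trough = min(float(smoothed[0]), 0.0)
    peak_idx = -1
    peak_val = 0.0
    for i, s in enumerate(smoothed):
        s = float(s)
        if peak_idx < 0:
            trough = min(trough, s)
            if s - trough >= params.min_prominence_pN and s >= params.min_prominence_pN:
                peak_idx, peak_val = i, s
        else:
            if s > peak_val:
                peak_idx, peak_val = i, s
            elif peak_val - s >= params.min_drop_pN:
                peaks.append(peak_idx)
                peak_idx = -1
                trough = s
    # refine each peak to the raw-force maximum near the smoothed maximum
    dx = float(np.median(np.diff(trace.extension_nm)))
    half = max(1, int(round(params.smooth_window_nm / dx)))
    refined = []
    for m in peaks:
        lo = max(0, m - half)
        hi = min(trace.n_samples, m + half + 1)
        refined.append(lo + int(np.argmax(trace.force_pN[lo:hi])))
    return sorted(set(refined))


def select_events(
    peaks: Sequence[int], trace: ForceExtensionTrace, params: DetectionParams
) -> tuple[list[int], bool]:
    """Drop the adhesion (first) and detachment (last) peaks.

    Returns the retained peak indices and whether the trace is accepted,
    i.e. whether at least ``min_events`` clear sequential unfolding events
    remain.
    """
    retained = list(peaks[1:-1]) if len(peaks) >= 2 else []
    return retained, len(retained) >= params.min_events


def _rising_window(
    trace: ForceExtensionTrace,
    peak_index: int,
    params: DetectionParams,
    prev_peak_index: int = 0,
) -> tuple[int, int]:
    """Sample window of the rising entropic-elasticity phase before a peak.

    Starts at the last upward crossing of ``engage_threshold_pN`` of the
    smoothed force before the peak (isolating one WLC branch); if the force
    never relaxes below the threshold after the previous rupture, the
    window starts at the force minimum after the previous peak instead.
    Ends at the peak (inclusive).
    """
    smoothed = _smooth(trace.force_pN, trace.extension_nm, params.smooth_window_nm)
    start = None
    for i in range(peak_index, prev_peak_index, -1):
        if smoothed[i - 1] < params.engage_threshold_pN <= smoothed[i]:
            start = i
            break
    if start is None:
        lo = min(prev_peak_index + 1, peak_index)
        start = lo + int(np.argmin(smoothed[lo : peak_index + 1]))
    return start, peak_index + 1


def fit_wlc_segment(
    trace: ForceExtensionTrace,
    peak_index: int,
    params: DetectionParams,
    consts: PhysicalConstants = PhysicalConstants(),
    p_nm: float = 0.36,
    prev_peak_index: int = 0,
) -> tuple[float, float] | None:
    """Least-squares WLC fit of one rising phase; returns (Lc_nm, rmse_pN).

    Only the contour length Lc is free; the persistence length stays fixed.
    Returns None (event discarded) if the window holds fewer than 5 samples
    or the fit does not converge.
    """
    start, stop = _rising_window(trace, peak_index, params, prev_peak_index)
    x = trace.extension_nm[start:stop]
    f = trace.force_pN[start:stop]
    if x.size < 5:
        logger.warning(
            "trace %s: rising window before sample %d has %d samples (<5); event discarded",
            trace.trace_id,
            peak_index,
            x.size,
        )
        return None
    x_max = float(x[-1])
    scale = consts.kBT_pNnm / p_nm

    def residuals(lc: np.ndarray) -> np.ndarray:
        t = x / lc[0]
        return scale * (0.25 / (1.0 - t) ** 2 - 0.25 + t) - f

    try:
        res = optimize.least_squares(
            residuals,
            x0=[1.3 * x_max],
            bounds=([x_max * (1.0 + 1e-9)], [50.0 * x_max]),
        )
    except Exception:
        logger.warning("trace %s: WLC fit raised at peak %d; event discarded",
                       trace.trace_id, peak_index)
        return None
    if not res.success:
        logger.warning("trace %s: WLC fit did not converge at peak %d; event discarded",
                       trace.trace_id, peak_index)
        return None
    lc = float(res.x[0])
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    return lc, rmse


def compute_event_metrics(
    trace: ForceExtensionTrace,
    events: list[UnfoldingEvent],
    consts: PhysicalConstants = PhysicalConstants(),
    accepted: bool = True,
) -> TraceAnalysis:
    """Assemble a :class:`TraceAnalysis`: ΔLc between sequential events.

    ΔLc_i = Lc_{i+1} − Lc_i over the retained (already fitted) events; a
    single retained event yields an empty ΔLc list.
    """
    delta = [events[i + 1].Lc_nm - events[i].Lc_nm for i in range(len(events) - 1)]
    return TraceAnalysis(trace=trace, events=events, delta_Lc_nm=delta, accepted=accepted)


def analyze_trace(
    trace: ForceExtensionTrace,
    params: DetectionParams = DetectionParams(),
    consts: PhysicalConstants = PhysicalConstants(),
    p_nm: float = 0.36,
    loading_rate_at: Literal["rupture", "window_mean"] = "rupture",
) -> TraceAnalysis:
    """Full per-trace analysis: detect, select, fit, measure.

    Loading rates are evaluated from the fitted WLC at each event's rupture
    point by default (``loading_rate_at="rupture"``), or at the mean
    extension of the fit window (``"window_mean"``).
    """
    peaks = detect_peaks(trace, params)
    retained, accepted = select_events(peaks, trace, params)
    events: list[UnfoldingEvent] = []
    for pk in retained:
        prev = max((p for p in peaks if p < pk), default=0)
        fit = fit_wlc_segment(trace, pk, params, consts, p_nm, prev_peak_index=prev)
        if fit is None:
            continue
        lc, rmse = fit
        start, stop = _rising_window(trace, pk, params, prev)
        x_peak = float(trace.extension_nm[pk])
        if loading_rate_at == "window_mean":
            x_eval = float(np.mean(trace.extension_nm[start:stop]))
        else:
            x_eval = x_peak
        lr = loading_rate(
            trace.pulling_speed_nm_s, min(x_eval, lc * (1 - 1e-9)),
            WLCParams(Lc_nm=lc, p_nm=p_nm), consts,
        )
        # the true rupture lies between the peak sample and the next one;
        # reading the fitted branch at the midpoint is unbiased in x
        step = float(np.median(np.diff(trace.extension_nm)))
        x_rup = min(x_peak + 0.5 * step, lc * (1 - 1e-9))
        f_rup = wlc_force(x_rup, WLCParams(Lc_nm=lc, p_nm=p_nm), consts)
        events.append(
            UnfoldingEvent(
                peak_force_pN=float(trace.force_pN[pk]),
                peak_extension_nm=x_peak,
                Lc_nm=lc,
                p_nm=p_nm,
                loading_rate_pN_s=lr,
                fit_rmse_pN=rmse,
                index_range=(start, stop),
                rupture_force_pN=float(f_rup),
            )
        )
    # two ruptures closer in contour length than the smallest measurable
    # feature are the same elastic branch seen twice (e.g. a noise spike on
    # the rising phase); keep the later, fuller rupture
    merged: list[UnfoldingEvent] = []
    for ev in events:
        if merged and ev.Lc_nm - merged[-1].Lc_nm < params.min_feature_nm:
            merged[-1] = ev
        else:
            merged.append(ev)
    events = merged
    accepted = accepted and len(events) >= params.min_events
    return compute_event_metrics(trace, events, consts, accepted)


# ---------------------------------------------------------------------------
# Plain-text I/O


def write_trace(trace: ForceExtensionTrace, path: str | Path) -> None:
    """Write a trace as `#key=value` headers plus two tab-separated columns."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#trace_id={trace.trace_id}\n")
        fh.write(f"#pulling_speed_nm_s={trace.pulling_speed_nm_s!r}\n")
        fh.write(f"#cantilever_k_N_m={trace.cantilever_k_N_m!r}\n")
        fh.write(f"#source={trace.source}\n")
        fh.write("#extension_nm\tforce_pN\n")
        for x, f in zip(trace.extension_nm, trace.force_pN):
            fh.write(f"{x:.6g}\t{f:.6g}\n")


def read_trace(path: str | Path) -> ForceExtensionTrace:
    """Read a trace written by :func:`write_trace`."""
    meta: dict[str, str] = {}
    xs: list[float] = []
    fs: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
            continue
        x_str, f_str = line.split("\t")
        xs.append(float(x_str))
        fs.append(float(f_str))
    return ForceExtensionTrace(
        extension_nm=np.array(xs),
        force_pN=np.array(fs),
        pulling_speed_nm_s=float(meta.get("pulling_speed_nm_s", 200.0)),
        cantilever_k_N_m=float(meta.get("cantilever_k_N_m", 0.025)),
        trace_id=meta.get("trace_id", Path(path).stem),
        source=meta.get("source", "experiment"),  # type: ignore[arg-type]
    )


def analyses_to_frame(analyses: Iterable[TraceAnalysis]) -> pd.DataFrame:
    """Flatten per-trace analyses into the tabular events schema."""
    rows = []
    for ana in analyses:
        for k, ev in enumerate(ana.events):
            rows.append(
                {
                    "trace_id": ana.trace.trace_id,
                    "event_index": k,
                    "peak_force_pN": ev.peak_force_pN,
                    "rupture_force_pN": ev.rupture_force_pN,
                    "peak_extension_nm": ev.peak_extension_nm,
                    "Lc_nm": ev.Lc_nm,
                    "loading_rate_pN_s": ev.loading_rate_pN_s,
                    "fit_rmse_pN": ev.fit_rmse_pN,
                    "accepted": ana.accepted,
                }
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(analyses: Iterable[TraceAnalysis], path: str | Path) -> pd.DataFrame:
    frame = analyses_to_frame(analyses)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
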