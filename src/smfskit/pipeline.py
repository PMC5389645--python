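"""End-to-end orchestration of the sawtooth analysis.

``run_pipeline`` chains the stages in analysis order — synthetic traces
(or traces from disk) → per-trace events → pooled (ΔLc, F) phase space →
two-Gaussian mixture fits — and writes plain-text artifacts plus a
key=value summary.  Every artifact carries a header with the tool version,
a hash of the configuration, and the master seed, so reruns are
diffable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

from . import __version__
from .ensemble import (
    build_phase_space,
    fit_two_gaussians,
    histogram_counts,
    pool_events,
)
from .synthetic import (
    EventFamily,
    TraceGenConfig,
    generate_ensemble,
    reference_truth_families,
    write_truth_fixture,
)
from .traces import (
    DetectionParams,
    analyses_to_frame,
    analyze_trace,
    read_trace,
    write_trace,
)

__all__ = ["run_pipeline", "config_hash"]

logger = logging.getLogger(__name__)


def config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(config: Mapping[str, Any], seed: int) -> str:
    return (
        f"#smfskit_version={__version__}\n"
        f"#config_hash={config_hash(config)}\n"
        f"#seed={seed}\n"
    )


def _gen_config(config: Mapping[str, Any]) -> TraceGenConfig:
    gen = dict(config.get("generator", {}))
    fams = gen.pop("families", None)
    if fams is None:
        families = tuple(reference_truth_families())
    else:
        families = tuple(EventFamily(**f) for f in fams)
    if "n_events_range" in gen:
        gen["n_events_range"] = tuple(gen["n_events_range"])
    return TraceGenConfig(families=families, **gen)


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Run traces → events → phase space → mixture fits; write artifacts.

    config keys (all optional except one source of traces):
      n_traces, seed        — synthetic ensemble size and master seed
      trace_dir             — read traces from disk instead of generating
      generator             — TraceGenConfig overrides (families, noise, ...)
      detection             — DetectionParams overrides
      condition_label       — label carried into the ensemble
      write_traces          — also write generated traces to outdir/traces/

    Returns the summary dict; artifacts: events.tsv, phase_space.tsv,
    truth_fixture.txt (synthetic runs), summary.txt.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    det = DetectionParams(**config.get("detection", {}))
    label = config.get("condition_label", "apo")

    truths = None
    if "trace_dir" in config:
        paths = sorted(Path(config["trace_dir"]).glob("*.txt"))
        if not paths:
            raise FileNotFoundError(f"no traces found in {config['trace_dir']}")
        traces = [read_trace(p) for p in paths]
        speed = traces[0].pulling_speed_nm_s
    else:
        gen_cfg = _gen_config(config)
        n_traces = int(config.get("n_traces", 300))
        traces, truths = generate_ensemble(gen_cfg, n_traces, seed)
        speed = gen_cfg.pulling_speed_nm_s
        write_truth_fixture(outdir / "truth_fixture.txt", gen_cfg.families)
        if config.get("write_traces", False):
            tdir = outdir / "traces"
            tdir.mkdir(exist_ok=True)
            for tr in traces:
                write_trace(tr, tdir / f"{tr.trace_id}.txt")

    analyses = [analyze_trace(tr, det) for tr in traces]
    header = _header(config, seed)

    frame = analyses_to_frame(analyses)
    with (outdir / "events.tsv").open("w") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t", index=False)

    ens = pool_events(analyses, condition_label=label, pulling_speed_nm_s=speed)
    if not ens.pairs:
        raise RuntimeError("ensemble stage: no (ΔLc, F) pairs from accepted traces")

    grid = build_phase_space(ens)
    with (outdir / "phase_space.tsv").open("w") as fh:
        fh.write(header)
        fh.write("#dlc_bin_start_nm\tforce_bin_start_pN\tcount\n")
        for dlc0, f0, c in grid.to_table():
            fh.write(f"{dlc0:g}\t{f0:g}\t{c}\n")

    dlc_centers, dlc_counts = histogram_counts(ens.delta_Lc_nm, grid.dlc_bin_nm)
    f_centers, f_counts = histogram_counts(ens.event_forces_pN, grid.force_bin_pN)
    dlc_fit = fit_two_gaussians(dlc_centers, dlc_counts)
    force_fit = fit_two_gaussians(f_centers, f_counts)

    summary: dict[str, Any] = {
        "condition_label": label,
        "n_traces": len(traces),
        "n_accepted": sum(a.accepted for a in analyses),
        "n_events": int(len(frame)),
        "n_pairs": len(ens.pairs),
        "dlc_center_low_nm": round(dlc_fit.centers[0], 4),
        "dlc_center_high_nm": round(dlc_fit.centers[1], 4),
        "dlc_p_value": float(f"{dlc_fit.separation_p_value:.6g}"),
        "force_center_low_pN": round(force_fit.centers[0], 4),
        "force_center_high_pN": round(force_fit.centers[1], 4),
        "force_p_value": float(f"{force_fit.separation_p_value:.6g}"),
    }
    if truths is not None:
        pooled = [ev for t in truths for ev in t.events]
        summary["truth_n_events"] = len(pooled)

    with (outdir / "summary.txt").open("w") as fh:
        fh.write(header)
        for key in sorted(summary):
            fh.write(f"{key}={summary[key]}\n")
    logger.info("pipeline complete: %s", summary)
    return summary
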