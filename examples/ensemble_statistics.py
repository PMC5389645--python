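"""Two-population statistics over a synthetic 300-trace ensemble.

Generates traces from the two-population ground truth (short ~16 nm
features rupturing at high force ~90 pN; full ~36 nm domains at ~40 pN),
pools all events into the (dLc, F) phase space binned 10 pN x 5 nm, and
fits the marginal histograms with two Gaussians.  The fitted centers
should recover the generating populations.
"""

from smfskit.ensemble import (
    build_phase_space,
    fit_two_gaussians,
    histogram_counts,
    pool_events,
)
from smfskit.synthetic import TraceGenConfig, generate_ensemble
from smfskit.traces import analyze_trace

traces, truths = generate_ensemble(TraceGenConfig(), n_traces=300, seed=7)
analyses = [analyze_trace(t) for t in traces]
ensemble = pool_events(analyses)
print(f"{len(traces)} traces, {sum(a.accepted for a in analyses)} accepted, "
      f"{len(ensemble.pairs)} (dLc, F) pairs")

grid = build_phase_space(ensemble)
print(f"phase-space grid: {grid.counts.shape[0]} x {grid.counts.shape[1]} cells "
      f"(5 nm x 10 pN), {grid.total} events")

centers, counts = histogram_counts(ensemble.delta_Lc_nm, 5.0)
dlc_fit = fit_two_gaussians(centers, counts)
print(f"\ndLc centers: {dlc_fit.centers[0]:.1f} and {dlc_fit.centers[1]:.1f} nm "
      f"(truth 16 and 36; separation p = {dlc_fit.separation_p_value:.1e})")

centers, counts = histogram_counts(ensemble.event_forces_pN, 10.0)
f_fit = fit_two_gaussians(centers, counts)
print(f"force centers: {f_fit.centers[0]:.1f} and {f_fit.centers[1]:.1f} pN "
      f"(truth 40 and 90; separation p = {f_fit.separation_p_value:.1e})")
print("\nThe low-dLc population carries the high forces: short, partially "
      "unfolded features resist more than whole domains.")
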