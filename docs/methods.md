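# Methods

This note records the models implemented, the numerical choices behind
them, and what the synthetic-data tests do and do not demonstrate.

## Worm-like-chain trace analysis

A force–extension sawtooth is modeled as a sequence of elastic branches.
Branch i obeys the interpolated WLC force law with contour length L_c,i
and fixed persistence length p = 0.36 nm; a rupture terminates the branch
and the next branch continues with a larger contour length. All
experimental-side quantities are in nm, pN and s, with k_BT = 4.1 pN·nm
(room temperature; no temperature parameter is exposed).

**Inverse WLC.** Extension at given force is found by bisection to a
1e-3·L_c bracket followed by safeguarded Newton iterations (fall back to
the bracket midpoint whenever a Newton step leaves it), converged to
relative 1e-9 in x **and** 1e-9 in residual force. The safeguard matters:
near L_c the force diverges and plain Newton overshoots.

**Peak detection** is hysteresis segmentation of the boxcar-smoothed
force: an excursion opens once the force has risen `min_prominence_pN`
(default 20) above the running trough — and stands at least that far above
the zero-force baseline — and its running maximum is emitted as a rupture
peak when the force has dropped `min_drop_pN` (default 15) below it. The
running trough initializes at min(first sample, 0) so a trace that starts
mid-rise still measures its first peak from the baseline. This
drop-oriented definition, rather than a two-sided topographic prominence,
is what a sawtooth needs: a genuine rupture whose following trough sits
high (a small ΔL_c released late in a trace) has little two-sided
prominence but an unambiguous force drop. Peak positions are refined to
the raw-force maximum within one smoothing window.

The boxcar width is `max(smooth_window_nm, adaptive)` where the adaptive
width is chosen so the smoothed residual noise (estimated robustly from
successive force differences) sits about five standard deviations below
the prominence threshold. Without adaptation, instrument-level noise
produces threshold-crossing excursions by chance; with it, detection
degrades gracefully as noise grows instead of fabricating events.

**Event selection.** The first peak (tip–surface adhesion) and the last
(detachment) are dropped; a trace is accepted only if ≥ `min_events`
(default 2) fitted events remain. Two fitted events whose contour lengths
differ by less than `min_feature_nm` (default 5 nm, the smallest
measurable ΔL_c feature) are one elastic branch seen twice — e.g. a noise
spike on a rising phase — and are merged, keeping the later rupture.

**WLC fits.** Each rising phase is fitted by least squares with L_c the
only free parameter, bounded below by the peak extension. The window runs
from the last upward crossing of `engage_threshold_pN` (default 10)
before the peak; when a late branch never relaxes below the threshold,
the window starts at the force minimum after the previous peak instead.
Windows of fewer than 5 samples are discarded with a logged warning.

**Rupture force.** Events carry two force estimates: the raw force at the
detected peak sample, and a sub-sample estimate — the fitted WLC branch
evaluated half a sampling step beyond the peak sample. The true rupture
lies uniformly between the last sampled point on the branch and the next
sample, so the raw readout is biased low by half a step times the local
slope (several pN on steep branches at 0.5 nm sampling); the midpoint
readout is unbiased and is what the ensemble statistics use.

**Loading rate** is evaluated analytically from the fitted branch at the
rupture point (config switch `loading_rate_at="window_mean"` evaluates at
the window's mean extension instead; the rupture-point slope is the
quantity that enters dynamic force spectroscopy).

## Ensemble statistics

ΔL_c,i = L_c,i+1 − L_c,i over sequential retained events. The phase-space
pair for interval i carries the force of the event terminating it; the
force *histograms*, however, pool the rupture forces of **all** retained
events — the forces measured are all used, and the first retained event
of each trace is typically its cleanest low-force detection.

Histograms use half-open bins with origin 0 (a value on an edge belongs
to the higher bin); default widths 10 pN and 5 nm. The two-Gaussian model
a₁N(c₁,s₁)+a₂N(c₂,s₂) is fitted to binned counts (not raw samples) by
nonlinear least squares from five deterministic starts — weighted 25th/
75th-percentile centers and ±1-bin perturbations — keeping the converged
fit with the lowest RMSE. The separation p-value is a two-sided t-test of
c₂−c₁ against zero using the fit covariance with (bins − 6) degrees of
freedom; centers collapsing within one bin flag a single population. The
Bell–Evans spectrum is fitted with k_u log-parameterized for positivity,
initialized from the log-linear slope.

## Coarse-grained pulling model

One bead per residue at the Cα position; reduced units Å, ε, τ with all
masses 1. Bonds k(r−r₀)² with k = 100 ε/Å², angles k(θ−θ₀)² with
k = 20 ε/rad², native-biased dihedrals k₁[1−cos(φ−φ₀)] + k₃[1−cos 3(φ−φ₀)]
with k₁ = 1, k₃ = 0.5 ε, native contacts ε[(r₀/r)¹² − 2(r₀/r)⁶] (depth −ε
exactly at r₀), and (4 Å/r)¹² repulsion between all other pairs separated
by ≥ 3 in sequence. Contacts come from a heavy-atom 4.5 Å distance
criterion (a proxy for surface-complementarity contact assignment, so
residue-level contact lists are approximate), or Cα 8 Å for bead-only
structures; r₀ is the native Cα–Cα distance. All constants are exposed in
`build_hamiltonian`.

The backbone torsion is undefined when three successive beads are
collinear; quadruples whose cross-product normals fall below |n|² =
0.25 Å⁴ are skipped (energy and force together). Near-native states of
real or toy structures never trigger this; fully stretched segments do,
where a torsion bias is meaningless anyway.

**Dynamics** is BAOAB Langevin splitting, dt = 0.005 τ, γ = 1/τ, default
kT = 1 ε (= the contact energy; exposed because folded-state stability at
this temperature must be checked per structure — the toy-structure tests
run at kT = 0.5 ε). With γ = 0 the scheme reduces exactly to velocity
Verlet; the conservation test measures the secular linear-fit drift of
total energy (< 1e-4 ε per 10⁴ steps), not the O(dt²) bounded
oscillation. Equilibration (default 10⁵ steps, springs static) precedes
pulling. The integrator and force kernels are numba-compiled; a fixed
seed gives bit-identical trajectories.

**Pulling protocol.** The C-terminal bead is held by a spring (1 ε/Å²) at
its native position; the pulling spring (K_p = 1 ε/Å²) attaches to a
configurable residue (N-terminal by default; a list of positions mimics
nonspecific tip attachment) and its base moves at v_p along the native
anchor→pull axis. Recorded force is K_p times the spring extension
projected on that axis. Simulated traces convert to experimental axes via
1 ε/Å = 41.7 pN and the pulled distance v_p·t as the extension
coordinate; rupture peaks are found with the same detector as
experimental traces (defaults there: 2 Å minimum smoothing, 30/20 pN
thresholds, above the residual thermal fluctuation of the spring), and
each peak is attributed to the domain whose end-to-end extension grows
most across the peak's force drop. Unfolding order is the order of first
attributed events.

## Synthetic data

The trace generator emulates: sequential WLC branches with cumulative
contour length (initial 30 nm), 2–4 events per trace drawn from a
two-population joint (ΔL_c, F) truth — (16±4 nm, 90±25 pN) and
(36±8 nm, 40±12 pN), equal weights, the short features paired with the
high forces — an adhesion spike near zero extension (60–150 pN), a
detachment rupture drawn from the high-force population, Gaussian force
noise (default 6 pN, below the ~10 pN cantilever thermal RMS), and 0.5 nm
extension sampling. Draws with non-positive values, or ruptures that fail
to advance along the extension axis, are redrawn (at most 100 attempts).
All randomness flows from one master seed through spawned per-trace
seeds, recorded in each truth record.

Not emulated: baseline drift, cantilever ringing, multiple tethers,
correlated (1/f) noise, vendor file formats. Passing recovery tests
therefore shows the estimator chain is consistent and unbiased under the
stated noise model, not that it is robust to every instrument artifact.

Noise robustness has a real ceiling: late low-force events can sit only a
few pN above their elevated post-rupture baseline, and no detector keeps
their counts stable under ±10 pN per-sample noise with 20/15 pN
thresholds. The robustness test therefore runs at the generator's default
6 pN noise; at the full thermal RMS the event count of marginal traces is
genuinely ambiguous.

Toy structures are β-meanders: strands of σ-spaced beads 5 Å apart joined
by single turn beads, pleated ±0.35 Å out of plane so no backbone torsion
is singular; domains stack along z with a 3-residue linker and exactly σ
spacing everywhere, far enough apart that no native contact crosses a
domain boundary. Per-domain contact-energy scaling creates constructs
with a known weaker domain.

## Problem sizes used in the tests

Mixture recovery runs 300 traces (the scale of the motivating
experiments); simulator physics uses a 30-residue domain and a 35-residue
two-domain construct pulled at v_p = 0.05 Å/τ (ten times the default
protocol speed) so a full unfolding fits in ~10⁶ steps; equipartition
statistics use 1.2·10⁶ steps of a single tethered bead. The real-protocol
speed and full-size structures run with the same code paths, only longer.

## Known limitations

- The contact criterion is a distance proxy; residue-level contact-change
  maps against surface-complementarity assignments agree qualitatively,
  not residue-for-residue.
- The two-Gaussian fit operates on binned counts; very sparse histograms
  (< 6 nonzero bins) are rejected rather than fitted.
- Ensemble pairing of ΔL_c with the terminating force is one convention
  for a scatter the source data leave ambiguous; the truth generator
  pairs (ΔL_c, F) within one event, so the phase-space *joint* structure
  of analysis and truth differ while all marginals agree.
- No extensible-WLC or freely-jointed-chain elasticity, no dual-barrier
  kinetic models, no force-clamp mode.
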