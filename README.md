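# smfskit

Single-molecule force spectroscopy of multidomain proteins, from both ends
of the experiment: analysis of AFM force–extension sawtooth curves, and
coarse-grained steered molecular dynamics that produces comparable curves
in silico. Written for the kind of study where a receptor ectodomain — the
motivating case is the interferon receptor IFNAR1, a tandem of FNIII
β-sandwich domains — is tethered between a surface and an AFM tip, pulled
at constant velocity, and its unfolding fingerprint compared between the
free and the ligand-bound state.

## What it computes

**Trace analysis.** Each rupture peak's rising phase is an entropic
elasticity branch described by the interpolated worm-like chain,

  F(x) = (k_BT/p) · [ 1/(4(1 − x/L_c)²) − 1/4 + x/L_c ],

with persistence length fixed at p = 0.36 nm and contour length L_c the
single free parameter (k_BT = 4.1 pN·nm). The increment ΔL_c between
sequential peaks measures the structure released per rupture. Loading
rates follow as lr = v · dF/dx at the rupture point. The first peak
(tip–surface adhesion) and the last (detachment) are excluded; a trace is
kept only if at least two clear sequential unfolding events remain.

**Ensemble statistics.** Pooled (ΔL_c, F) pairs form a phase space binned
at 10 pN × 5 nm — the force bin is the cantilever thermal force RMS
√(k_c·k_BT), the ΔL_c bin the smallest measurable length feature. The
marginal histograms are fitted with two Gaussians to extract the most
probable force F_p and ΔL_c of each population, and across pulling speeds
the (loading rate, F_p) points are fitted with the Bell–Evans model
F_p = (k_BT/x_u)·ln(x_u·lr/(k_BT·k_u)).

**Go-model pulling.** A structure becomes a Cα bead chain (σ = 3.6 Å)
with native contacts (heavy-atom 4.5 Å proxy, or Cα 8 Å for bead-only
structures) attracting through 12-6 Lennard-Jones wells of uniform depth
ε = 0.6 kcal/mol; everything else repels. BAOAB Langevin dynamics with a
fixed C-terminal spring and a pulling spring moving at v_p (default
5·10⁻³ Å/τ, K_p = 1 ε/Å², τ = σ√(m/ε) ≈ 1 ps) reproduces the sawtooth
with per-domain attribution of every rupture.

**Contact changes.** Per-residue counts of intra-chain contacts in a free
vs a bound structure, classified gained/lost — the structural origin of a
binding-induced change in mechanical stability.

**Synthetic data.** A seeded generator stands in for the instrument:
multi-event WLC sawtooths drawn from a two-population (ΔL_c, F) truth
(16 nm/90 pN and 36 nm/40 pN), with thermal force noise, adhesion and
detachment peaks; plus multi-domain β-meander toy structures with defined
contacts for simulator tests.

## Worked example

```sh
python examples/ensemble_statistics.py
```

prints (seed 7, 300 traces):

```
300 traces, 262 accepted, 416 (dLc, F) pairs
phase-space grid: 19 x 16 cells (5 nm x 10 pN), 416 events

dLc centers: 15.6 and 37.5 nm (truth 16 and 36; separation p = 1.5e-15)
force centers: 40.4 and 88.3 pN (truth 40 and 90; separation p = 5.0e-08)
```

The full pipeline — peak detection, WLC fits, ΔL_c bookkeeping, histogram
mixture fits — recovers the two generating populations: a narrowly
distributed ~16 nm feature that ruptures at high force, and a broad ~36 nm
population (a full domain) at ~40 pN. The other scripts in `examples/`
each exercise one capability: `wlc_basics.py` (closed forms and units),
`analyze_sawtooth.py` (one trace), `pull_toy_protein.py` (a two-domain
pulling simulation with unfolding order), `contact_changes.py` (free vs
bound contact profiles).

A thin CLI wraps the same functions for shell use:
`smfskit gen-traces | analyze | ensemble | dfs | build-model | pull |
contact-delta | pipeline` (see `--help`).

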