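"""Worm-like-chain elasticity and the constants behind the analysis.

Evaluates the closed-form pieces every other example builds on: the WLC
force-extension law, the loading rate at a rupture point, the Bell-Evans
most-probable force, the cantilever thermal force noise that sets the
10 pN histogram bin, and the coarse-grained time and force units.
"""

import math

from smfskit.polymer import (
    BellEvansParams,
    WLCParams,
    bell_evans_force,
    cg_time_unit,
    loading_rate,
    sim_force_to_pN,
    thermal_force_rms,
    wlc_force,
    wlc_inverse_extension,
)

wlc = WLCParams(Lc_nm=36.0)  # one unfolded domain's worth of contour length

print("WLC force at half the contour length:",
      f"F(18 nm; Lc=36, p=0.36) = {wlc_force(18.0, wlc):.2f} pN")
print("Extension where the chain reaches 100 pN:",
      f"x = {wlc_inverse_extension(100.0, wlc):.2f} nm")
print("Loading rate at that point when pulling at 200 nm/s:",
      f"lr = {loading_rate(200.0, wlc_inverse_extension(100.0, wlc), wlc):.0f} pN/s")

be = BellEvansParams(xu_nm=0.5, ku_per_s=0.1)
print("Bell-Evans most probable force at lr = 100 pN/s:",
      f"Fp = {bell_evans_force(100.0, be):.1f} pN",
      "(grows by kBT/xu = 8.2 pN per e-fold in lr)")

kc_mid = math.sqrt(0.018 * 0.038)  # geometric mean of the stiffness range
print("Cantilever thermal force RMS over the 0.018-0.038 N/m range:",
      f"{thermal_force_rms(0.018):.1f}-{thermal_force_rms(0.038):.1f} pN;",
      f"at the geometric mean {thermal_force_rms(kc_mid):.1f} pN",
      "-> the 10 pN force histogram bin")

print(f"Coarse-grained time unit tau = {cg_time_unit():.3e} s (~1 ps)")
print(f"Coarse-grained force unit 1 eps/A = {sim_force_to_pN(1.0):.1f} pN")
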