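"""Stopped-flow shrinkage trace → biexponential fit → both P_f models.

Simulates a liposome-shrinkage experiment with a known channel
permeability, fits the two-rate model, and converts the fast rate k2 to
osmotic permeability with the conventional and the corrected estimator.
"""

from cageflux import (
    ShrinkageGroundTruth,
    VesicleSpec,
    estimate_permeability,
    fit_biexponential,
    simulate_shrinkage,
)

# 200-nm vesicles, 0.2 Osm/L sucrose inside, 0.4 Osm/L outside after
# 1:1 mixing with the hypertonic osmolyte
vesicle = VesicleSpec(diameter_nm=200.0, c_in0_osm=0.2, c_out_osm=0.4)

# ground truth: 70% of vesicles carry channels adding 300 μm/s on top of
# a 10 μm/s lipid background; 1% measurement noise
truth = ShrinkageGroundTruth(
    pf_lipid_um_s=10.0, pf_channel_um_s=300.0,
    channel_fraction=0.7, noise_sd=0.01, seed=42,
)

result = simulate_shrinkage(vesicle, truth, duration_s=2.0)
fit = fit_biexponential(result.trace)
perm = estimate_permeability(fit.k2, vesicle)

print(f"fitted rates:  k1 = {fit.k1:6.2f} s^-1 (lipid bilayer)")
print(f"               k2 = {fit.k2:6.2f} s^-1 (channel pathway)")
print(f"conventional P_f = {perm.pf_conventional_um_s:6.1f} um/s")
print(f"corrected    P_f = {perm.pf_corrected_um_s:6.1f} um/s "
      f"(x{perm.correction_factor} correction)")
print(f"true channel-population P_f = "
      f"{truth.pf_lipid_um_s + truth.pf_channel_um_s:.0f} um/s")
# The corrected estimate should sit close to the true 310 um/s, while
# the conventional one overshoots ~2.7-fold: the conventional model
# assumes the osmotic gradient never relaxes during shrinkage.
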