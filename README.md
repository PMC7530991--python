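# cageflux

Analysis toolkit for evaluating **porous organic cages (POCs) as synthetic
water channels** in lipid membranes. It implements the quantitative chain
from raw stopped-flow liposome-shrinkage traces to per-nanoaggregate water
throughput, plus the trajectory statistics used to characterise water
confined in the cage channel network.

Intended users: membrane-biophysics and materials groups running
liposome-reconstitution permeability assays, and simulation groups
post-processing channel-hydration trajectories.

## The models

**Shrinkage kinetics.** Exposing liposomes to a hypertonic osmolyte drives
water efflux; the 90° light-scattering signal is fitted with a
double-exponential,

```
y(t) = y∞ − a₁ e^(−k₁ t) − a₂ e^(−k₂ t),
```

where k₁ is permeation through the bare lipid bilayer and k₂ (the faster
rate) is permeation through the embedded channels.

**Osmotic permeability.** Two estimators convert k₂ (s⁻¹) to P_f (μm s⁻¹)
for a spherical vesicle with S/V₀ = 3/r and molar water volume
V_w = 0.018 L mol⁻¹:

```
conventional:  P_f = k₂ / ((S/V₀) · V_w · Δ_osm)
corrected:     P_f = k₂ / ((S/V₀) · V_w) × (c_in,0 + c_out) / (2 c_out²)
```

The conventional form assumes the initial gradient Δ_osm = c_out − c_in,0
persists for the whole transient; the corrected form (after Pohl and
co-workers) accounts for the concentrating vesicle interior and recovers
the true permeability from a rate fitted over the full shrinkage.

**Nanoaggregate counting.** Cage molecules aggregate into membrane-spanning
nanocrystals (17 cages per aggregate; 75 for the large-window cage). The
"unit area" A_Unit = A_POC + ((1−x)/x)·0.35 nm² tiles the liposome area
A_Total = 2πr² + 2π(r−5)², giving N = A_Total/A_Unit aggregates per
liposome (halved for membrane-spanning channels). The per-aggregate
permeability is P_a = P_f·A/N, converted to waters s⁻¹ via N_A/18 cm³ mol⁻¹.

**Hydration statistics.** From per-frame water coordinates: occupancy
probability P(n_w) of the channel's 1-nm middle segment, wetting–dewetting
episode kinetics, single-file water-chain extraction from the hydrogen-bond
graph with dipolar-order scoring, and potential-energy barrier profiles
along the channel axis.

A seeded synthetic-data module generates all three input kinds (shrinkage
traces, two-state occupancy series, branched water-wire frames) with known
ground truth for parameter-recovery testing.

## Worked example

```bash
python examples/shrinkage_to_permeability.py
```

```
fitted rates:  k1 =   2.78 s^-1 (lipid bilayer)
               k2 =  90.60 s^-1 (channel pathway)
conventional P_f =  838.9 um/s
corrected    P_f =  314.6 um/s (x0.375 correction)
true channel-population P_f = 310 um/s
```

The trace was simulated with a known channel-population permeability of
310 μm s⁻¹. The corrected estimator lands within 2% of the truth, while
the conventional estimator overshoots ~2.7-fold — exactly the bias the
corrected model exists to remove. Under the standard assay conditions
(0.2 Osm L⁻¹ sucrose inside, 0.4 Osm L⁻¹ outside after 1:1 mixing) the
correction factor is Δ_osm(c_in,0+c_out)/(2c_out²) = 0.375.

`examples/single_aggregate_permeability.py` continues the chain: a 200-nm
liposome at 0.03 cage/lipid feed ratio carries N ≈ 271 aggregates, and a
bulk permeability of 359 μm s⁻¹ corresponds to ≈ 5.3×10⁹ waters s⁻¹ per
aggregate (conventional) or ≈ 2.0×10⁹ (corrected) — aquaporin-scale
throughput. `examples/hydration_statistics.py` demonstrates the
trajectory statistics.

A thin CLI mirrors the library (`cageflux fit-trace`, `cageflux
permeability`, `cageflux aggregate-perm`, `cageflux hydration`,
`cageflux pipeline`, and the `simulate-*` generators).

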