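# Methods

This note records the models behind `cageflux`, the choices made where a
convention was genuinely open, and what the synthetic-data generators do
and do not emulate.

## Vesicle shrinkage model

A vesicle of initial volume V₀ and surface area S (both from the outer
DLS diameter; the package does not attempt an inner-leaflet correction)
shrinks under an outward osmotic gradient according to

    dV/dt = −P_f · S · V_w · (c_out − c_in,0 · V₀/V),

with V_w = 0.018 L mol⁻¹ (not temperature-corrected) and the
intravesicular osmolyte conserved, so its concentration scales as
V₀/V. The reduced form in v = V/V₀ is integrated with adaptive
Runge–Kutta (RK45, rtol 1e−9, atol 1e−12) so that integration error is
negligible against fitting error. The solution decays monotonically to
the osmotic equilibrium v∞ = c_in,0/c_out.

The light-scattering signal of a shrinkage experiment is modelled as
proportional to the fractional volume loss, 1 − V/V₀, linearly rescaled
to [0, 1] over the analysis window (exposed as a flag, since only rate
constants — not amplitudes — feed the permeability models; a full
Rayleigh–Gans–Debye form factor is out of scope). The biexponential
character of measured traces is reproduced by a mixture of two vesicle
subpopulations: a channel-bearing fraction φ with
P_f = P_f,lipid + P_f,channel and a channel-free fraction 1 − φ with
P_f,lipid alone. This is a modelling device that yields a genuinely
two-rate signal; it is not a claim about the physical origin of the
second rate in any particular dataset.

Default generator conditions mirror the standard assay: 2-s window,
400 samples, c_in,0 = 0.2 Osm L⁻¹ and c_out = 0.4 Osm L⁻¹ (1:1
stopped-flow mixing of 200 mM internal sucrose with 600 mM hypertonic
osmolyte; sucrose osmotic coefficient taken as 1), Gaussian additive
noise. What the generator does not emulate: vesicle size polydispersity,
multi-lamellarity, instrument dead time, shot-noise statistics, and
scattering-form-factor nonlinearity. Passing recovery tests therefore
demonstrates estimator correctness under the model's assumptions, not
robustness to every artefact of real stopped-flow data.

## Biexponential fitting

y(t) = y∞ − a₁e^(−k₁t) − a₂e^(−k₂t), bounds a ≥ 0 and k > 0 (rates are
optimised in log space). Initialisation is by exponential peeling — the
slow rate from a log-linear fit of the tail residual, the fast rate from
the decaying head of what remains — with log-linear fits restricted to
samples that clear a robust noise floor (3× the MAD of first differences
divided by √2), since the flat post-decay tail otherwise corrupts the
slopes. Eight multistarts jitter the rate pair by log-uniform factors in
[0.3, 3] (plus one deterministic ×10 fast start); the lowest-residual
solution wins.

Rate assignment: the channel pathway is faster than the lipid
background, so after fitting the rates are relabelled with k₂ =
max(k₁, k₂); the rule is recorded on the fit object. Degenerate fits are
flagged, never silently returned: rate collapse (|k₂−k₁|/k₂ < 1e−3) or a
fast amplitude below 3× the noise floor ("no channel component",
blank-liposome behaviour); a slow amplitude below the floor also flags
an effectively single-exponential trace. A fixed-k₁ mode supports
pinning the lipid rate from a blank control; both free- and fixed-k₁
fits are available because published workflows differ on this point.

## Permeability models

Conventional: P_f = k₂/((S/V₀)·V_w·Δ_osm). Corrected (Pohl):
P_f = k₂/((S/V₀)·V_w) × (c_in,0+c_out)/(2c_out²). Concentrations are
carried in Osm L⁻¹ and converted to mol m⁻³ internally; results are in
μm s⁻¹. The ratio corrected/conventional is the dimensionless factor
Δ_osm(c_in,0+c_out)/(2c_out²), exactly 0.375 at the standard conditions;
the package asserts exact proportionality to machine precision.

Numerical validation (run by the test suite): on noiseless simulated
shrinkage over a 3×3 grid of true P_f ∈ {100, 300, 600} μm s⁻¹ and
diameter ∈ {100, 150, 200} nm, fitting a single exponential and applying
the corrected model recovers the truth within ~4%, while the
conventional model overestimates ~2.7-fold — the corrected estimator is
strictly closer in every cell. Optional blank subtraction (lipid-only
background permeability) is provided but off by default, since reporting
conventions vary.

## Nanoaggregate counting and P_a

The counting model is implemented literally:
A_Total = 2πr² + 2π(r−5)² with r in nm and 5 nm the bilayer thickness.
Note 2πr² is *half* a sphere's area: A_Total is half the sum of the
outer- and inner-leaflet sphere areas. We keep the printed form for
internal consistency and flag it here rather than "fixing" it. The feed
mole ratio is corrected to aggregates per lipid, x = fmCLR/n_aggregate
(17 cages per aggregate; 75 for the large cage), and
A_Unit = A_POC + ((1−x)/x)·0.35 nm². N = A_Total/A_Unit, halved by
default on the reading that a membrane-spanning aggregate occupies both
leaflets; `halving` is an explicit flag because the halving convention
and the area entering P_a = P_f·A/N interact. Two area conventions are
implemented (`eq3_total`, the default, and `sphere` = 4πr²).

Useful identity: with halving and A = A_Total, P_a = 2·P_f·A_Unit
exactly — independent of the liposome radius. This makes the
per-aggregate conversion insensitive to the (unreported) DLS radius,
which is why corrected/conventional *ratios* of P_a are robust even
though absolute forward reconstruction of a printed P_a requires a
radius assumption. Conversion to waters s⁻¹ uses N_A/(18 cm³ mol⁻¹)
≈ 3.346×10²².

## Hydration statistics

Occupancy: n_w counts water oxygens whose axial coordinate (default
axis z, the membrane normal; configurable for branched networks where
"the" channel axis is ambiguous) falls in a half-open segment [lo, hi) —
a 1-nm window centred on the oxygens' mean axial position by default.
Half-open bounds guarantee a boundary water is counted exactly once when
segments tile the axis. The histogram mode ties break toward the
smallest n_w, so an always-dry channel reports 0.

Wetting–dewetting: frames with n_w ≤ threshold (default 0) are "empty";
episodes are maximal runs. Dwell means exclude the first and last
episodes (censored at the record boundaries); rates are reciprocal mean
dwells. The CTMC generator also returns the underlying continuous
episode durations so goodness-of-fit against the exponential dwell law
can be tested without discretisation bias.

Chains: hydrogen-bond adjacency uses O–O ≤ 3.5 Å and, when hydrogens are
present, a donor O–H···O angle ≥ 140° (conventional water H-bond
geometry; both configurable — the source trajectories do not fix a
criterion). Waters of degree ≥ 3 are branch nodes; the graph decomposes
into maximal simple paths, each reported node-first, no two chains
sharing an edge. A degree-2 junction (two arms) yields one through-going
chain. Dipolar order is the mean cosine of the donated O→H bond against
the local chain tangent (±1 for a perfectly ordered wire); the donated
bond is identified per O–O contact as the hydrogen pointing at the
acceptor. Other dipole conventions (e.g. the full molecular dipole
vector) would shrink |order| below 1 even for ideal wires; the donated-
bond convention keeps the ordered-wire signature crisp.

The chain generator places waters on tetrahedral arm directions with a
shared node water for ≥ 2 arms; at most two arms may be oriented
"outward" because the node has only two hydrogens to donate — a real
geometric constraint of branched water wires, enforced rather than
fudged. Default arm orientations alternate, reproducing the
opposite-orientation arrangement of neighbouring chains.

Energy profiles: per-position potential-energy series are averaged over
their trailing window — the last ⌈(1−f)·n⌉ samples with equilibration
fraction f = 0.5 by default (matching the convention of averaging the
last 500 ps of a 1-ns run). Barriers are differences between consecutive
labelled positions; a mirror-symmetry flag (absolute tolerance
configurable) marks symmetric profiles. The series are inputs: no
energies are computed here.

## Problem sizes and determinism

Every stochastic path is driven by an explicit integer seed through
`numpy.random.default_rng`; identical inputs give bit-identical outputs.
The test suite uses 10⁵-frame occupancy runs for rate recovery (3
standard errors), a 3×3 ODE grid for estimator recovery, and 20 random
tuples for the counting-model oracle — sizes chosen so the whole suite
runs in a few seconds while keeping statistical tests well-powered.

## Known limitations

- The scattering model is linear in volume loss; amplitude-dependent
  quantities (not used by the permeability chain) are not meaningful.
- The subpopulation-mixture origin of biexponentiality is one of several
  plausible mechanisms; only the rates are interpreted.
- The counting model inherits the literal A_Total expression discussed
  above; absolute P_a values depend on an assumed liposome radius unless
  the radius-independent halving + A_Total combination is used.
- Chain extraction assumes single-file topology (paths); dense bulk-like
  water in large-cavity cages produces high-degree graphs for which a
  path decomposition is not a meaningful description.
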