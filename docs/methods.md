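# Methods

## Model class and feature conditions

The package analyses deterministic ODE models in Gujer/Petersen-matrix form,
`dx/dt = M·r(x) + z`, with `x ∈ R^N` the states, `r(x) ∈ R^R` the kinetic
rates, `M ∈ R^(N×R)` the stoichiometric matrix and `z` an exogenous
actuation vector (here: oxygen transfer by aeration acting on dissolved
oxygen). Applying the chain rule once gives the second time derivative
`d²x/dt² = M·J_r·dx/dt + ż` with `J_r = ∂r/∂x`; substituting the model
equation for `dx/dt` eliminates all derivative symbols, so both feature
conditions become closed-form expressions in states, parameters and
actuation. This substitution is what makes locus screening possible without
integrating the ODEs: the locus of a ramp of signal `x_i` is simply
`{x : (M·r + z)_i > 0 ∧ (M·J_r·(M·r + z) + ż)_i = 0}`.

Saddle points are excluded by the strict inequality: states with
`dx_i/dt = 0` are extrema (valleys/peaks, also supported), not ramps.
Uniform time rescaling (all rates and `z` multiplied by c > 0) scales the
first derivative by c and the second by c², leaving the locus set unchanged;
the test suite checks this numerically.

## ASM1 variants

Two Activated Sludge Model No. 1 definitions ship as built-ins.

* `original13` — the classical 13-state, 8-process matrix with Henze-style
  state names (`S_S, X_BH, S_O, …`).
* `mbc14` — a mass-balance-corrected variant with 14 states and descriptive
  names (`S_b, X_h, S_O2, …`). Relative to the original it adds dinitrogen
  `S_N2` as an explicit state so anoxic heterotrophic growth conserves
  nitrogen, and an ammonia nutrient-limitation Monod factor
  `S_NHx/(S_NHx + K_NH_H)` on heterotrophic growth so biomass synthesis
  requires a nitrogen source. All other processes mirror the original
  matrix. Nitrogen continuity closes exactly per process (tested); COD
  continuity including oxygen and nitrogen electron equivalents closes to
  ~0.1%, the residual being the conventional rounded denitrification factor
  2.86 vs the exact 40/14 g COD (g N)⁻¹.

Default parameters are the widely used 20 °C values of the original ASM1
report, stored in `src/gujerdsa/data/asm1_parameters_20C.csv` with units and
descriptions. The nitrate COD conversion factor is taken as
`i_COD_NO3 = −64/14 ≈ −4.57 g COD (g N)⁻¹`; with it, both multipliers of
the oxygen-consuming growth rates in `dS_O2/dt`,
`(Y_A + i_COD_NO3)/Y_A` and `(Y_H − 1)/Y_H`, are negative for any plausible
yields — oxygen is only consumed biologically, so a dissolved-oxygen ramp
requires aeration (`z_O2 > 0`). This is also proved structurally at run
time by term-sign inspection over the non-negative orthant (best effort:
parameters are substituted numerically, states get non-negativity
assumptions, and each additive term of the first derivative must be provably
non-positive; when inconclusive, feasibility is decided by sampling).

A documentation note: the eight causes of the dissolved-oxygen ramp are
`S_O2, S_NHx, S_NOx, S_bN, S_b, X_a, X_cb, X_h`. Particulate biodegradable
organic nitrogen `X_cbN` is *not* a cause — it influences only the
hydrolysis of organic nitrogen, which feeds states that do not enter the
oxygen balance's dependency cone. Statements that count `X_cbN` among the
alternative causes conflate the nine dynamic-core states with the eight
condition states.

## Dependency graph and causal diagram

The dependency graph is bipartite: state → rate when the state occurs in the
rate expression, rate → state when the stoichiometric entry is structurally
non-zero (decided symbolically, so a zero-valued parameter does not delete
an edge). States with at least one outgoing edge form the dynamic core;
states only written to are measurement-only; isolated states are uncoupled.
For the `mbc14` variant this yields 9 / 3 / 2 respectively.

A feature's causal diagram takes the states occurring in the symbolic
conditions as parents of the feature node. Parent–parent adjacency uses
one-rate-hop influence (A occurs in a rate with non-zero stoichiometry on
B); transitive influence would make almost every pair adjacent and empty the
immorality set. Immoralities are the non-adjacent parent pairs, reported in
lexicographic order. The number of V-structures of the dissolved-oxygen ramp
diagram (five under these semantics) is a computed output, cross-checked in
the tests by brute-force enumeration of all C(8,2) pairs.

## State-space screening

The ramp locus has measure zero, so uniform sampling alone never hits it.
The scan fixes all causal states but one per draw and solves the
second-derivative equality along the remaining *solve variable* (default:
the signal itself, dissolved oxygen): the equality is evaluated on a
257-node grid over the solve range, sign changes are refined by bisection to
~1e-10 in solve-variable units (grid nodes that hit the root exactly count
as on-locus), and roots with strictly positive first derivative become ramp
points. Residuals are accepted relative to the magnitude of the equality
along the sample's grid row (`|d²x/dt²| ≤ 1e-8·(1 + scale)`), since the
expression's terms reach ~1e6 g m⁻³ d⁻² at high aeration and biomass.
Points are labelled true positive when the target (ammonium) is at or below
the threshold — inclusive comparison, 1 g m⁻³ by default.

Default sampling ranges (`src/gujerdsa/data/asm1_scan_default.yaml`) are
wide-but-feasible literature ranges for municipal SBR operation, in g m⁻³:
S_b, X_cb ∈ [0, 200]; X_h ∈ [300, 3000]; X_a ∈ [10, 300]; S_O2 ∈ [0, 10];
S_NOx ∈ [0, 50]; S_NHx ∈ [0, 200]; S_bN ∈ [0, 30]. The biomass lower bounds
reflect that a sequencing batch reactor retains settled sludge between
cycles and never operates near zero biomass; the remaining states may
deplete fully. Aeration `z_O2` is sampled uniformly in [0, 2000] g m⁻³ d⁻¹
(mass-transfer coefficients up to ~200 d⁻¹ at ~10 g m⁻³ saturation deficit)
with `ż_O2 = 0`, i.e. piecewise-constant aeration between switches; whether
to fix or sample the aeration is a config choice recorded in the run
manifest. The actuation is consumed directly as `z`; a controller input
model `z = b(u)` is out of scope.

With these defaults, a 10,000-sample scan yields ~8,000 ramp points, the
vast majority false positives — ammonium is uniform on [0, 200], so draws at
or below 1 g m⁻³ are rare (~0.5%), and the true-positive set is accordingly
small (~10 points). Statistics of the TP set, such as the maximum S_bN
reported by `scripts/acceptance.py`, therefore fluctuate noticeably between
seeds; they estimate the bulk of the TP distribution rather than its exact
supremum. Within the TP set, high soluble organic nitrogen is systematically
absent (≈7 g m⁻³ and above): ammonification `k_a·S_bN·X_h` regenerates
ammonium, so at operating biomass a low-ammonium ramp is only consistent
with moderate S_bN. The slope-retention table quantifies the complementary
pattern that false positives concentrate at small oxygen slopes: above
400 g m⁻³ d⁻¹ the retained FP fraction is ~0.3%, while part of the TP set
is lost as well.

Inflection-point curves in a 2-D plane are extracted by marching squares
(scikit-image, linear interpolation) on a 512² grid by default. Because the
first derivative can change sign within a fraction of a grid cell near the
locus, every contour vertex is polished by bisection along a plane axis
before the strict `dx_i/dt > 0` mask is applied; vertices are clamped into
the plane rectangle so boundary artefacts at exactly zero oxygen (where the
derivative is 0, not positive) are excluded.

## Simulation oracle

The integrator (SciPy LSODA, rtol 1e-8 / atol 1e-10 by default) serves as an
independent numeric route: piecewise-constant actuation schedules restart
integration at each switch, and non-negative states are clamped at zero in
the output because tolerance-level undershoot flips the sign of Monod terms
and fabricates positive oxygen derivatives. Trajectory ramp detection uses
central differences with sign-change bracketing; identically-zero
second-derivative segments (straight-line signal) report no ramp, crossings
within a half-window of an aeration switch are excluded (the actuation
derivative is impulsive there), and the interpolated slope must exceed a
noise floor of 1e-6 times the trajectory's peak slope — strict positivity is
not meaningful at differencing-noise level. On SBR scenarios the numeric
detections and the symbolic condition crossings coincide with zero
mismatches at 4,001-point grids (tested across seeds); a 5-point moving
average is available for noisy synthetic signals, though process/measurement
noise is otherwise outside the scope of this deterministic analysis.

The `asm1_sbr` fixture draws its initial state from the screening ranges
(re-drawing biomass into the upper 80% of its range, as an SBR carries
sludge between cycles) and aerates intermittently in four quarter-day
phases, as typical for an SBR; no attempt is made to reproduce any specific
published trajectory, and assertions about it are structural (detection
agreement, aeration necessity), not about particular ramp times.

## Known limitations

* Alkalinity and pH do not influence any ASM1 rate, so no analysis on this
  model can surface alkalinity-driven ramps; a model that represents the
  coupling (e.g. ASM3-type) would be needed, and only the ASM1 definitions
  ship here.
* The screening results are conditional on the sampling ranges; the shipped
  ranges are literature-based defaults and fully editable, and
  range-sensitive statistics should be read as distributional patterns, not
  sharp bounds.
* Structural infeasibility proofs are best-effort term-sign inspection;
  inconclusive cases fall back to sampling evidence.
* Hydrolysis kinetics are indeterminate at exactly zero biomass and zero
  substrate (0/0 in the saturation term); screening and simulation operate
  away from that corner, and evaluation there returns NaN rather than a
  fabricated value.
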