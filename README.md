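# gujerdsa

Dynamical-systems analysis of biokinetic models in Gujer/Petersen-matrix
form, aimed at qualitative-trend soft-sensor development for water and
resource-recovery processes.

Many wastewater soft sensors infer a hard-to-measure quantity (e.g. effluent
ammonium) from a *feature* of an easy signal (e.g. a ramp in dissolved
oxygen). Such features can have alternative causes: other state variables
that produce the same signal shape and therefore false predictions. For any
model of the form

```
dx/dt = M·r(x) + z
```

— `M` the N×R stoichiometric (Gujer/Petersen) matrix, `r(x)` the R kinetic
rate expressions, `z` an exogenous actuation such as aeration — the second
time derivative follows from the chain rule without any integration:

```
d²x/dt² = M·J_r·(M·r(x) + z) + ż
```

with `J_r` the Jacobian of the rates. A **ramp** (non-saddle inflection) of
signal `x_i` is the locus `dx_i/dt > 0 ∧ d²x_i/dt² = 0`; both sides are
closed-form in states, parameters and actuation. This package derives those
conditions symbolically, reads off the feature's *causal parents* and their
*immoralities* (V-structures — non-adjacent co-parents whose conditional
association enables false positives), and screens state space for
true/false-positive feature points. The Activated Sludge Model No. 1 ships
as a built-in, both the original 13-state form and a 14-state
mass-balance-corrected variant, and any other matrix-structured model can be
supplied as a Petersen-matrix CSV.

## Worked example

Causes of the dissolved-oxygen ramp in the mass-balance-corrected ASM1:

```
$ gujerdsa causes -m mbc14 -o out/causes
feature: ramp of S_O2
causes (8): S_NHx, S_NOx, S_O2, S_b, S_bN, X_a, X_cb, X_h
non-causes: S_N2, S_alk, S_nb, X_cbN, X_nb_e, X_nb_in
immoralities (5):
  S_NHx -- X_cb
  S_b -- S_bN
  S_b -- X_a
  S_bN -- X_a
  X_a -- X_h
```

Eight of the fourteen states can cause the ramp — not only the ammonium the
soft sensor wants to infer. Particulate biodegradable organic nitrogen
(`X_cbN`) is dynamic but *not* a cause, and the five immoralities (e.g.
autotrophs `X_a` with heterotrophs `X_h`) are exactly the configurations in
which a data-driven detector can be fooled. A state-space scan quantifies
the risk:

```
$ gujerdsa scan -m mbc14 -o out/scan --n 2000 --seed 1
1681 ramp points from 2000 samples: 2 TP, 1679 FP (target S_NHx <= 1.0)
```

Each ramp point is a state assignment solving the two conditions (found by
bisection along dissolved oxygen), labelled true positive (TP) when ammonium
is at or below the 1 g m⁻³ depletion threshold. `out/scan/retention.csv`
reports how a minimum-slope filter changes the balance: above an oxygen
slope of 400 g m⁻³ d⁻¹ almost no false positives survive. A time-domain
cross-check integrates a sequencing-batch-reactor scenario and detects ramps
the traditional way:

```
$ gujerdsa simulate --fixture asm1_sbr --seed 0 -o out/sim
5 ramp(s) of S_O2 at: 0.0137, 0.5141, 0.5959, 0.6927, 0.6961
```

Every detected time satisfies the symbolic conditions, and no ramp ever
occurs while aeration is off (`z_O2 = 0`): without an oxygen source, every
term of `dS_O2/dt` is non-positive and the ramp is structurally impossible.

Other commands: `gujerdsa graph` (dependency graph, DOT/GraphML, state
classification), `gujerdsa locus` (inflection-point curves in a 2-D state
plane). All runs write a `manifest.json` with seed, config and parameter
hash for exact reproduction.

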