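# Default state-space scan for the dissolved-oxygen ramp of the
# mass-balance-corrected ASM1.
#
# Ranges are wide-but-feasible literature ranges for municipal activated
# sludge / SBR operation (g m-3; aeration in g O2 m-3 d-1):
#   S_b    readily biodegradable COD, raw-to-settled sewage levels
#   X_cb   slowly biodegradable COD entering the reactor
#   X_h    heterotrophic biomass: an operating SBR retains settled sludge
#          between cycles, so the lower bound is a low-MLSS operating level,
#          not zero; upper bound is high-MLSS operation
#   X_a    autotrophic (nitrifying) biomass, a few percent of total biomass,
#          likewise retained between cycles
#   S_O2   up to clean-water oxygen saturation (~10)
#   S_NOx  nitrate+nitrite levels up to heavily nitrified liquor
#   S_NHx  ammonium from depletion up to concentrated streams (0-200)
#   S_bN   soluble biodegradable organic nitrogen
#   z_O2   oxygen transfer rate: K_La up to ~200 d-1 at ~10 g m-3 deficit
model: mbc14
signal: S_O2
feature: ramp
seed: 0
n: 10000
solve_variable: S_O2
target_variable: S_NHx
threshold: 1.0
plane: [S_O2, S_NHx]
grid_nodes: 257
ranges:
  S_b: [0.0, 200.0]
  X_cb: [0.0, 200.0]
  X_h: [300.0, 3000.0]
  X_a: [10.0, 300.0]
  S_O2: [0.0, 10.0]
  S_NOx: [0.0, 50.0]
  S_NHx: [0.0, 200.0]
  S_bN: [0.0, 30.0]
actuation:
  z_O2: [0.0, 2000.0]
slope_thresholds: [0.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1600.0]
min_slope: null
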