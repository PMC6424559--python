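# Human-derived running control gains (left-stance canonical values),
# nondimensional (lengths in maximum leg lengths, velocities in
# sqrt(g * leg length), impulses mass-normalized).
#
# fp_vx : sideways foot placement per unit apex sideways-velocity deviation
# fp_vy : fore-aft foot placement per unit apex fore-aft-velocity deviation
# fp_za : fore-aft foot placement per unit apex height deviation
# ll_za : landing leg length per unit apex height deviation
# K_target : measured right-to-left apex-return map on (vx, vy, z) deviations;
#            K_significant flags entries distinguishable from zero (p < 0.05).
# reference : companion regression values from the same human dataset
#             (right-stance values and impulse slopes), kept for comparison
#             and symmetry checks; not used by the controller.
fp_vx: 0.95
fp_vy: 0.42
fp_za: -0.76
ll_za: 0.3
K_target:
- [-0.05, -0.02, 0.31]
- [-0.08, 0.27, -0.15]
- [0.02, 0.06, 0.46]
K_significant:
- [false, false, false]
- [false, true, true]
- [false, true, true]
zero_nonsignificant: false
G: null
reference:
  impulse_vx: {left: -1.03, right: -1.07, r2: [0.55, 0.53]}
  impulse_vy: {left: -0.72, right: -0.72, r2: [0.32, 0.33]}
  half_impulse_za: {left: 2.5, right: 2.3, r2: [0.35, 0.30]}
  landing_length_za: {value: 0.3, r2: 0.25}
  fp_vx: {left: 0.95, right: 1.00, r2: [0.64, 0.62]}
  fp_vy: {left: 0.42, right: 0.39, r2: [0.45, 0.46]}
  fp_za: {left: -0.76, right: -0.83}
  stride_max_eigenvalue_unrounded: 0.14
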