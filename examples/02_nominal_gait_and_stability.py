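"""Solve a periodic running gait and test its stability with and without
the human-derived controller.

The nominal gait matches target speed, step period, step width and peak leg
force; landing occurs at 95% of maximum leg length.  Without feedback the
periodic motion is unstable (stride spectral radius > 1); with foot-placement,
landing-leg-length and force feedback fitted to the human apex-return map it
becomes strongly stable.
"""

import numpy as np

from runcontrol.control import (
    Controller,
    fit_force_gains,
    solve_nominal_gait,
    stride_jacobian,
)

gait = solve_nominal_gait(variant="force")
print(f"periodic gait solved: residual {gait.residual:.1e}")
print(f"  Tstance={gait.Tstance:.3f}  Tflight={gait.Tflight:.3f}  "
      f"A1={gait.A1:.3f}  A2={gait.A2:.3f}  peak force={gait.peak_force:.2f} bw")

open_loop = stride_jacobian(gait, None)
print(f"\nopen loop (no feedback): stride spectral radius "
      f"{open_loop['spectral_radius']:.2f}  -> unstable")

gains = fit_force_gains(gait)
ctrl = Controller(gait, gains)
closed = stride_jacobian(gait, ctrl)
print(f"closed loop (fitted controller): stride spectral radius "
      f"{closed['spectral_radius']:.3f}  -> stable")
print("one-step apex-return map (canonical frame):")
print(np.array_str(closed["K_canonical"], precision=3, suppress_small=True))
print("target map from human running:")
print(np.array_str(gains.K_canonical, precision=3, suppress_small=True))
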