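"""Vertical position control with a triangular stance force.

Between two flight apexes the net vertical impulse always equals the gravity
impulse, so apex height can only be steered by redistributing impulse within
the step.  For an impulse-balanced triangular force profile the peak force is
exactly 2 body weights, and shifting the peak later lowers the next apex.
"""

import numpy as np

from runcontrol.vertical import (
    apex_height_change,
    half_impulse_split,
    tpeak_for_height_change,
    triangular_peak_force,
)

Tstep = 1.0  # nondimensional step duration

print(f"peak force: {triangular_peak_force(Tstep):.1f} body weights (any Tstep)")
print(f"{'tpeak':>8} {'dz_next_apex':>14} {'P_first_half':>13} {'P_second_half':>14}")
for tpeak in np.linspace(0.2, 0.8, 7):
    dz = apex_height_change(Tstep, tpeak)
    p1, p2 = half_impulse_split(Tstep, tpeak)
    print(f"{tpeak:8.2f} {dz:+14.5f} {p1:13.4f} {p2:14.4f}")

# invert: which peak timing lowers the next apex by 5 mm on a 1 m leg?
tp = tpeak_for_height_change(Tstep, -0.005)
print(f"\nto lower the next apex by 0.005 leg lengths: tpeak = {tp:.4f} "
      f"(after mid-stance, as expected)")
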