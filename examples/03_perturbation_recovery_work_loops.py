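"""Perturbation recovery and the leg work needed to achieve it.

A runner that rejects energy-changing perturbations cannot be a passive
spring: the first recovery step performs net (here negative) leg work.
Sideways velocity errors are corrected almost deadbeat (one step); fore-aft
errors take two to three steps.
"""

import numpy as np

from runcontrol.control import Controller, fit_force_gains, solve_nominal_gait
from runcontrol.simulate import simulate_run, work_loop
from runcontrol.states import ApexState

gait = solve_nominal_gait(variant="force")
ctrl = Controller(gait, fit_force_gains(gait))
nominal_apex = gait.apex_state("left")

for label, (dvx, dvy, dza) in {
    "sideways velocity +0.10": (0.10, 0.0, 0.0),
    "forward velocity +0.10": (0.0, 0.10, 0.0),
    "apex height +0.05": (0.0, 0.0, 0.05),
}.items():
    apex = ApexState(
        xa=0.0, ya=0.0, za=nominal_apex.za + dza,
        vxa=nominal_apex.vxa + dvx, vya=nominal_apex.vya + dvy, side="left",
    )
    recs = simulate_run(gait, ctrl, n_steps=4, initial_apex=apex)
    devs = [np.linalg.norm(gait.canonical_deviation(r.apex_out, r.apex_out.side))
            for r in recs]
    _, _, w = work_loop(recs[0])
    print(f"{label}:")
    print("  |apex deviation| after each step: "
          + "  ".join(f"{d:.4f}" for d in devs))
    print(f"  net leg work on first step: {recs[0].net_leg_work:+.4f} "
          f"(work-loop trapezoid: {w:+.4f})")
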