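"""Generate an experiment-like noisy running dataset.

The muscle-driven biped runs a few hundred steps under calibrated motor
noise (one multiplicative draw per stance on the activation profile, plus
additive foot-placement noise).  The emitted dataset mimics a split-belt
treadmill recording: per-belt GRFs at a 1000 Hz-equivalent clock and
marker-like kinematics at 100 Hz, with measurement noise.  The apex-state
variability is not prescribed — it emerges from noise filtered through the
closed-loop dynamics.
"""

import numpy as np

from runcontrol import synthetic as syn

cfg = syn.GeneratorConfig(variant="muscle", n_steps=300, seed=12)
ds, truth = syn.generate_dataset(cfg)

print(f"steps completed: {ds.meta['n_steps']}  fell: {ds.meta['fell']}")
print(f"force channel: {len(ds.t_force)} samples at "
      f"{cfg.dt_force_s*1e3:.0f} ms;  kinematics: {len(ds.t_kin)} samples")
dev = truth.steps[["dvx_c", "dvy_c", "dza"]].to_numpy()
sd = dev.std(axis=0)
print("emergent apex-state s.d. (nondim): "
      f"sideways vel {sd[0]:.4f}, fore-aft vel {sd[1]:.4f}, height {sd[2]:.4f}")
print(f"height s.d. in mm on a {ds.scales.leg_length_m:.2f} m leg: "
      f"{sd[2]*ds.scales.leg_length_m*1e3:.1f}")

# write it like a lab trial (forces.tsv, kin.tsv, meta.json in SI units)
syn.write_dataset(ds, "scratch/example_trial")
print("wrote scratch/example_trial/ (forces.tsv, kin.tsv, meta.json)")
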