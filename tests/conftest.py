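"""Shared fixtures: solved gaits, fitted controllers, and synthetic datasets.

The expensive artifacts (nominal gaits, the 2000-step muscle-variant
recovery dataset) are session-scoped and shared across test modules.
"""

import numpy as np
import pytest

import runcontrol as rc
from runcontrol import inference as inf
from runcontrol import synthetic as syn
from runcontrol.control import Controller, NoiseSpec, fit_force_gains
from runcontrol.simulate import simulate_run
from runcontrol.states import ApexState

#: seed of the packaged recovery run (the study conditions, not a dial)
RECOVERY_SEED = 1
RECOVERY_STEPS = 2000


@pytest.fixture(scope="session")
def force_gait():
    return rc.solve_nominal_gait(variant="force")


@pytest.fixture(scope="session")
def muscle_gait():
    return rc.solve_nominal_gait(variant="muscle")


@pytest.fixture(scope="session")
def force_gains(force_gait):
    return fit_force_gains(force_gait)


@pytest.fixture(scope="session")
def muscle_gains(muscle_gait):
    return fit_force_gains(muscle_gait)


@pytest.fixture(scope="session")
def force_controller(force_gait, force_gains):
    return Controller(force_gait, force_gains)


@pytest.fixture(scope="session")
def muscle_controller(muscle_gait, muscle_gains):
    return Controller(muscle_gait, muscle_gains)


@pytest.fixture(scope="session")
def small_dataset(force_gait, force_gains):
    """300 noisy direct-force steps: fast, for pipeline unit tests."""
    cfg = syn.GeneratorConfig(variant="force", n_steps=300, seed=42, gains=force_gains)
    return syn.generate_dataset(cfg, nominal=force_gait)


@pytest.fixture(scope="session")
def clean_dataset(force_gait, force_gains):
    """Noise-free periodic running, no measurement noise: the degenerate
    reference for event/feature checks."""
    cfg = syn.GeneratorConfig(
        variant="force", n_steps=60, seed=3, gains=force_gains,
        noise=NoiseSpec(0.0, 0.0, 0.0),
        meas_noise_force_bw=0.0, meas_noise_pos=0.0,
    )
    return syn.generate_dataset(cfg, nominal=force_gait)


@pytest.fixture(scope="session")
def recovery_dataset(muscle_gait, muscle_gains):
    """The packaged parameter-recovery run: 2000 noisy muscle-variant steps
    at calibrated noise."""
    cfg = syn.GeneratorConfig(
        variant="muscle", n_steps=RECOVERY_STEPS, seed=RECOVERY_SEED,
        gains=muscle_gains,
    )
    return syn.generate_dataset(cfg, nominal=muscle_gait)


@pytest.fixture(scope="session")
def recovery_analysis(recovery_dataset):
    ds, _ = recovery_dataset
    return inf.analyze(ds)


def perturbed_step_outputs(nominal, controller, dev, n_steps=1):
    """Simulate from a perturbed left apex; used as a finite-difference
    oracle for the model's true sensitivities."""
    a = nominal.apex_state("left")
    a = ApexState(xa=0.0, ya=0.0, za=a.za + dev[2],
                  vxa=a.vxa + dev[0], vya=a.vya + dev[1], side="left")
    return simulate_run(nominal, controller, n_steps=n_steps,
                        initial_apex=a, record_series=True)


def half_impulses(rec, threshold=0.05):
    """First/second-half vertical stance impulse from a step record.

    Uses the same stance-window convention as the inference pipeline (the
    vertical-GRF detection threshold): for the muscle variant the force can
    dwell below threshold near takeoff, so the window convention materially
    changes the half-impulse sensitivities and the oracle must match it.
    """
    from scipy.integrate import cumulative_trapezoid

    t, fz = rec.t_series, rec.grf_series[:, 2]
    above = np.flatnonzero(fz > threshold)
    a, b = t[above[0]], t[above[-1]]
    c = cumulative_trapezoid(fz, t, initial=0.0)
    mid = 0.5 * (a + b)
    p1 = float(np.interp(mid, t, c) - np.interp(a, t, c))
    p2 = float(np.interp(b, t, c) - np.interp(mid, t, c))
    return p1, p2


@pytest.fixture(scope="session")
def muscle_impulse_oracle(muscle_gait, muscle_controller, recovery_dataset):
    """Noise-free Monte-Carlo oracle for the emergent impulse sensitivities.

    The impulse responses are mildly nonlinear over the operating range, so
    the honest expected value for a regression estimate is the average slope
    over the actual apex-state cloud: re-simulate a sample of the recovery
    run's own apex deviations with the noise turned off and regress the
    resulting impulses on the same deviations.  Returns per-output parameter
    vectors (dvx, dvy, dza) and their standard errors.
    """
    import pandas as pd
    import statsmodels.api as sm

    _, truth = recovery_dataset
    devs = truth.steps[truth.steps.side == "left"].iloc[:150]
    rows = []
    for _, row in devs.iterrows():
        rec = perturbed_step_outputs(
            muscle_gait, muscle_controller, (row.dvx_c, row.dvy_c, row.dza)
        )[0]
        p1, p2 = half_impulses(rec)
        # leg length at the detected stance start (threshold crossing), the
        # quantity the pipeline's landing-length regression actually measures
        t_star = rec.t_series[np.flatnonzero(rec.grf_series[:, 2] > 0.05)[0]]
        pos = np.array([np.interp(t_star, rec.t_series, rec.state_series[:, j])
                        for j in range(3)])
        ll = float(np.linalg.norm(pos - rec.foot.pos))
        rows.append(dict(dvx=row.dvx_c, dvy=row.dvy_c, dza=row.dza,
                         Px=rec.Px, Py=rec.Py, Pz1=p1, Pz2=p2, ll=ll))
    df = pd.DataFrame(rows)
    X = sm.add_constant(df[["dvx", "dvy", "dza"]] - df[["dvx", "dvy", "dza"]].mean())
    out = {}
    for col in ("Px", "Py", "Pz1", "Pz2", "ll"):
        fit = sm.OLS(df[col] - df[col].mean(), X).fit()
        out[col] = {
            "params": fit.params.drop("const"),
            "bse": fit.bse.drop("const"),
        }
    return out
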