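"""Hybrid dynamics of the 3D point-mass biped runner.

The body is a point mass on a massless telescoping leg: parabolic free
flight, stance under a scalar axial leg force, with touchdown when the
body-to-target-foot distance equals the commanded landing leg length and
takeoff when the leg regains its maximum length (l = 1).  Nondimensional
units throughout (m = g = l_max = 1); see :mod:`runcontrol.states`.

Stance is integrated with an adaptive high-order Runge-Kutta scheme
(DOP853, rtol 1e-10) with terminal event localization; the within-stance
impulse components and the leg work ``int F dl`` ride along as extra
quadrature states so they share the integrator's accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .states import ApexState, BodyState, FootAnchor, StepRecord, Terrain

__all__ = [
    "SimConfig",
    "flight_to_event",
    "stance_derivative",
    "integrate_stance",
    "simulate_run",
    "work_loop",
]

#: leg length at takeoff (maximum leg length, the length unit)
L_MAX = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Integrator tolerances and fall criteria (all configurable; the fall
    thresholds are package choices, not measured quantities)."""

    rtol: float = 1e-10
    atol: float = 1e-12
    z_fall: float = 0.2          # body below this height => fallen
    l_collapse: float = 0.1      # leg shorter than this => fallen
    stance_time_factor: float = 3.0   # stance longer than this x nominal => fallen
    dt_sample: float = 2.5e-3    # sampling interval for recorded series
    event_tol: float = 1e-12


DEFAULT_SIM = SimConfig()


def stance_derivative(state: BodyState, foot: FootAnchor, Fleg: float) -> np.ndarray:
    """Time derivative of (pos, vel) during stance.

    Acceleration is ``Fleg`` along the unit foot-to-body vector minus
    gravity: m x'' = Fleg (x - xfoot)/l, ..., m z'' = -m g + Fleg (z - zfoot)/l.
    """
    p = state.pos - foot.pos
    l = float(np.linalg.norm(p))
    if l <= 0.0:
        raise ValueError("singular leg configuration: zero leg length")
    acc = Fleg * p / l
    acc[2] -= 1.0
    return np.concatenate([state.vel, acc])


def _flight_distance_poly(state: BodyState, foot: FootAnchor) -> np.ndarray:
    """Descending coefficients of the quartic d(t)^2 along the flight parabola."""
    dx = np.array([0.0, state.vx, state.x - foot.xfoot])
    dy = np.array([0.0, state.vy, state.y - foot.yfoot])
    dz = np.array([-0.5, state.vz, state.z - foot.zfoot])
    out = np.zeros(5)
    for c in (dx, dy, dz):
        out += np.convolve(c, c)
    return out


def flight_to_event(
    state: BodyState,
    target_foot: FootAnchor,
    landing_length: float,
    config: SimConfig = DEFAULT_SIM,
) -> tuple[BodyState, str]:
    """Propagate ballistic flight to the first of apex or touchdown.

    Touchdown is the first instant where the distance from the body to the
    target foot equals ``landing_length`` with the body descending onto the
    leg.  If the body is at apex (``vz <= 0`` on entry) and the distance is
    already below the landing length, touchdown is immediate.  Returns the
    event state and one of ``"apex" | "touchdown" | "fell"``.
    """
    if not (0.0 < landing_length <= L_MAX):
        raise ValueError("landing_length must be in (0, 1]")
    d0 = float(np.linalg.norm(state.pos - target_foot.pos))
    if state.vz <= config.event_tol and d0 <= landing_length + 1e-9:
        return state, "touchdown"
    if abs(state.vz) <= config.event_tol:
        return state, "apex"  # entering at apex with the foot out of reach

    # quartic |body(t) - foot|^2 - landing_length^2 = 0
    poly = _flight_distance_poly(state, target_foot)
    poly[-1] -= landing_length**2
    roots = np.roots(poly)
    dpoly = np.polyder(poly)
    candidates = []
    for r in roots:
        if abs(r.imag) > 1e-9 or r.real < -1e-12:
            continue
        t = max(r.real, 0.0)
        if np.polyval(dpoly, t) < 0:  # distance decreasing: descending onto the leg
            candidates.append(t)
    t_td = min(candidates) if candidates else None

    t_apex = state.vz if state.vz > config.event_tol else None
    if t_apex is not None and (t_td is None or t_apex < t_td - config.event_tol):
        return state.advance_ballistic(t_apex), "apex"
    if t_td is not None:
        # reject touchdown below ground level of the target foot
        s = state.advance_ballistic(t_td)
        if s.z >= target_foot.zfoot - 1e-9:
            return s, "touchdown"
    # no usable touchdown: ballistic until the body would pass the foot height
    disc = state.vz**2 + 2.0 * (state.z - target_foot.zfoot)
    t_fall = state.vz + np.sqrt(max(disc, 0.0))
    return state.advance_ballistic(t_fall), "fell"


def integrate_stance(
    state0: BodyState,
    foot: FootAnchor,
    force_profile: Callable[[float, float, float], float],
    t_max: float,
    config: SimConfig = DEFAULT_SIM,
    record_series: bool = True,
) -> StepRecord:
    """Integrate one stance phase until takeoff at maximum leg length.

    ``force_profile(t, l, l_rate)`` returns the scalar leg force (rectified
    here to be non-negative); ``t`` is time since touchdown.  The returned
    :class:`StepRecord` fragment carries the stance trajectory, GRF samples,
    impulses, and net leg work; ``fell`` is set if the body drops below the
    fall height, the leg collapses, or no takeoff occurs within ``t_max``.
    """
    fp = foot.pos

    def rhs(t, y):
        p = y[0:3] - fp
        l = np.sqrt(p @ p)
        v = y[3:6]
        ldot = (p @ v) / l
        F = max(force_profile(t, l, ldot), 0.0)
        u = p / l
        return np.array(
            [v[0], v[1], v[2],
             F * u[0], F * u[1], F * u[2] - 1.0,
             F * u[0], F * u[1], F * u[2],
             F * ldot]
        )

    def ev_takeoff(t, y):
        p = y[0:3] - fp
        return np.sqrt(p @ p) - L_MAX

    def ev_fall(t, y):
        return y[2] - config.z_fall

    def ev_collapse(t, y):
        p = y[0:3] - fp
        return np.sqrt(p @ p) - config.l_collapse

    ev_takeoff.terminal, ev_takeoff.direction = True, 1.0
    ev_fall.terminal, ev_fall.direction = True, -1.0
    ev_collapse.terminal, ev_collapse.direction = True, -1.0

    y0 = np.concatenate([state0.pos, state0.vel, np.zeros(4)])
    sol = solve_ivp(
        rhs, (0.0, t_max), y0, method="DOP853",
        rtol=config.rtol, atol=config.atol, dense_output=True,
        events=[ev_takeoff, ev_fall, ev_collapse],
    )
    fell, reason = False, ""
    if len(sol.t_events[0]) > 0:
        t_end = float(sol.t_events[0][0])
    elif len(sol.t_events[1]) > 0:
        t_end, fell, reason = float(sol.t_events[1][0]), True, "fell below minimum height"
    elif len(sol.t_events[2]) > 0:
        t_end, fell, reason = float(sol.t_events[2][0]), True, "leg collapsed"
    else:
        t_end, fell, reason = float(sol.t[-1]), True, "stance exceeded maximum duration"

    y_end = sol.sol(t_end)
    rec = StepRecord(
        index=-1, side="", apex_in=None, apex_out=None, foot=foot,
        t_touchdown=state0.t, t_takeoff=state0.t + t_end, Tstance=t_end,
        landing_length=float(np.linalg.norm(state0.pos - fp)),
        Px=float(y_end[6]), Py=float(y_end[7]), Pz=float(y_end[8]),
        net_leg_work=float(y_end[9]), fell=fell, fall_reason=reason,
    )
    rec._end_state = BodyState(*y_end[0:6], t=state0.t + t_end)
    if record_series:
        n = max(int(np.ceil(t_end / config.dt_sample)), 8)
        ts = np.linspace(0.0, t_end, n + 1)
        ys = sol.sol(ts)
        p = ys[0:3] - fp[:, None]
        l = np.sqrt((p * p).sum(axis=0))
        ldot = (p * ys[3:6]).sum(axis=0) / l
        F = np.array(
            [max(force_profile(t, li, ld), 0.0) for t, li, ld in zip(ts, l, ldot)]
        )
        rec.t_series = ts + state0.t
        rec.grf_series = (F / l)[:, None] * p.T  # components F * unit vector
        rec.leg_length_series = l
        rec.state_series = ys[0:6].T
    return rec


def work_loop(step: StepRecord) -> tuple[np.ndarray, np.ndarray, float]:
    """Force-vs-leg-length curve of a stance and its net work.

    Returns ``(leg_length, leg_force, net_work)`` where net work is the
    trapezoid integral of F dl over the recorded samples (positive = energy
    added by the leg).
    """
    if step.leg_length_series.size == 0:
        raise ValueError("step has no recorded stance series")
    F = np.linalg.norm(step.grf_series, axis=1)
    l = step.leg_length_series
    net = float(np.trapezoid(F, l))
    return l, F, net


def simulate_run(
    nominal,
    controller=None,
    noise=None,
    terrain: Optional[Terrain] = None,
    n_steps: int = 10,
    rng: Optional[np.random.Generator] = None,
    config: SimConfig = DEFAULT_SIM,
    record_series: bool = True,
    initial_apex: Optional[ApexState] = None,
    periodicity_tol: float = 1e-4,
    apex_offsets: Optional[np.ndarray] = None,
) -> list[StepRecord]:
    """Simulate ``n_steps`` alternating left/right steps in closed loop.

    Each step runs apex -> touchdown -> stance -> takeoff -> next apex.  The
    control action for the coming stance (foot placement, landing leg
    length, force/activation coefficients) is chosen at flight apex; when
    the body leaves the ground moving downward there is no apex and the
    end-of-stance state is used instead.  Stops early (with ``fell`` set on
    the last record) if the runner falls.

    ``controller`` defaults to the purely nominal (feedforward) command;
    ``noise`` is a :class:`runcontrol.control.NoiseSpec` applied per stance.
    ``apex_offsets`` adds per-step vertical position offsets at flight apex
    (cycled if shorter than the run) — the apex-state equivalent of running
    over uneven terrain; ``terrain`` instead offsets the foot height at
    touchdown.
    """
    from . import control as _control  # deferred: avoid import cycle

    if nominal.residual > periodicity_tol:
        raise ValueError(
            f"nominal gait periodicity residual {nominal.residual:.2e} exceeds "
            f"{periodicity_tol:.0e}; refusing to simulate"
        )
    rng = rng or np.random.default_rng(0)
    apex = initial_apex or nominal.apex_state("left")
    records: list[StepRecord] = []
    t_stance_max = config.stance_time_factor * nominal.Tstance

    for k in range(n_steps):
        side = apex.side
        if apex_offsets is not None and len(apex_offsets) > 0:
            from dataclasses import replace as _rep
            apex = _rep(apex, za=apex.za + float(apex_offsets[k % len(apex_offsets)]))
        if controller is not None:
            cmd = controller.command(apex, side)
        else:
            cmd = _control.nominal_command(nominal, side)
        if noise is not None:
            cmd = _control.apply_noise(cmd, noise, rng)

        zfoot = terrain.height(k, apex.ya) if terrain is not None else 0.0
        body = apex.as_body_state()
        # closed-form flight to touchdown at the commanded *relative* placement:
        # the body descends to height zc above the foot, the foot is then at
        # the commanded offset from the COM
        rx, ry = cmd.rel_foot
        arg = cmd.landing_length**2 - rx**2 - ry**2
        if arg <= 0:
            rec = StepRecord(index=k, side=side, apex_in=apex, apex_out=None,
                             foot=None, fell=True,
                             fall_reason="commanded placement exceeds leg length")
            records.append(rec)
            break
        zc = zfoot + np.sqrt(arg)
        disc = body.vz**2 + 2.0 * (body.z - zc)
        if body.z <= zc or disc < 0:
            t_td = 0.0  # already below the landing sphere: immediate stance
        else:
            t_td = body.vz + np.sqrt(disc)
        td = body.advance_ballistic(t_td)
        foot = FootAnchor(td.x + rx, td.y + ry, zfoot)

        frag = integrate_stance(
            td, foot, cmd.force_fn(), t_stance_max, config, record_series
        )
        end = frag._end_state
        if not frag.fell and end.vz > config.event_tol:
            apex_next_body = end.advance_ballistic(end.vz)
            true_apex = True
        else:
            apex_next_body, true_apex = end, False
        next_side = "right" if side == "left" else "left"
        apex_out = ApexState(
            xa=apex_next_body.x, ya=apex_next_body.y, za=apex_next_body.z,
            vxa=apex_next_body.vx, vya=apex_next_body.vy,
            side=next_side, is_true_apex=true_apex, t=apex_next_body.t,
            vza=0.0 if true_apex else apex_next_body.vz,
        )
        rec = StepRecord(
            index=k, side=side, apex_in=apex, apex_out=apex_out, foot=foot,
            t_touchdown=td.t, t_takeoff=frag.t_takeoff, Tstance=frag.Tstance,
            Tflight=t_td + (end.vz if true_apex else 0.0),
            landing_length=frag.landing_length,
            t_series=frag.t_series, grf_series=frag.grf_series,
            leg_length_series=frag.leg_length_series,
            state_series=frag.state_series,
            Px=frag.Px, Py=frag.Py, Pz=frag.Pz,
            net_leg_work=frag.net_leg_work,
            fell=frag.fell, fall_reason=frag.fall_reason, command=cmd,
        )
        records.append(rec)
        if rec.fell:
            break
        apex = apex_out
    return records


def steps_to_frame(records: Sequence[StepRecord]):
    """One row per step: apex states, impulses, placement, durations, work.
    Serializable to TSV with ``DataFrame.to_csv(..., sep="\\t")``."""
    import pandas as pd

    rows = []
    for r in records:
        a, o = r.apex_in, r.apex_out
        rows.append({
            "index": r.index, "side": r.side, "fell": r.fell,
            "apex_t": a.t, "apex_x": a.xa, "apex_y": a.ya, "apex_z": a.za,
            "apex_vx": a.vxa, "apex_vy": a.vya, "apex_true": a.is_true_apex,
            "apex_out_z": np.nan if o is None else o.za,
            "apex_out_vx": np.nan if o is None else o.vxa,
            "apex_out_vy": np.nan if o is None else o.vya,
            "foot_x": np.nan if r.foot is None else r.foot.xfoot,
            "foot_y": np.nan if r.foot is None else r.foot.yfoot,
            "foot_z": np.nan if r.foot is None else r.foot.zfoot,
            "t_touchdown": r.t_touchdown, "t_takeoff": r.t_takeoff,
            "Tstance": r.Tstance, "Tflight": r.Tflight,
            "landing_length": r.landing_length,
            "Px": r.Px, "Py": r.Py, "Pz": r.Pz,
            "net_leg_work": r.net_leg_work,
        })
    return pd.DataFrame(rows)


def trajectory_to_frame(records: Sequence[StepRecord]):
    """Stance-phase trajectory samples of a run: time, COM state, GRF, leg
    length, and a phase label, one row per sample."""
    import pandas as pd

    parts = []
    for r in records:
        if r.t_series.size == 0:
            continue
        df = pd.DataFrame(r.state_series, columns=["x", "y", "z", "vx", "vy", "vz"])
        df.insert(0, "t", r.t_series)
        df[["Fx", "Fy", "Fz"]] = r.grf_series
        df["leg_length"] = r.leg_length_series
        df["phase"] = f"stance_{r.side}"
        df["step"] = r.index
        parts.append(df)
    return pd.concat(parts, ignore_index=True)
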