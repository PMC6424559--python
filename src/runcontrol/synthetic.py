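"""Experiment-like synthetic gait datasets from the noisy closed-loop model.

Emulates the structure of a split-belt treadmill running recording: per-belt
3D ground reaction forces on a fast clock (1000 Hz equivalent) and
marker-like kinematics — a COM proxy and one marker per foot — on a slow
clock (100 Hz equivalent), with optional measurement noise and slow force
drift.  Step-to-step variability is not injected into the channels; it
emerges from motor noise (multiplicative force/activation noise, additive
foot-placement noise) interacting with the closed-loop dynamics.

Every generated dataset ships with a ground-truth bundle (the gains and
noise actually used, plus per-step true states and commands) so that
inference results can be checked by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .control import (
    Controller,
    GainSet,
    NoiseSpec,
    NominalGait,
    default_gains,
    fit_force_gains,
    solve_nominal_gait,
)
from .muscle import MuscleParams
from .simulate import DEFAULT_SIM, SimConfig, simulate_run
from .states import Scales, StepRecord, Terrain

__all__ = [
    "GeneratorConfig",
    "GaitDataset",
    "GroundTruthBundle",
    "generate_dataset",
    "synth_swing_trajectory",
    "write_dataset",
    "read_dataset",
    "load_external",
]

SCHEMA_VERSION = 1

_FORCE_COLS = ["time", "flx", "fly", "flz", "frx", "fry", "frz"]
_KIN_COLS = [
    "time",
    "com_x", "com_y", "com_z",
    "lfoot_x", "lfoot_y", "lfoot_z",
    "rfoot_x", "rfoot_y", "rfoot_z",
]
_META_KEYS = ["mass_kg", "g", "leg_length_m", "speed_mps", "schema_version", "seed", "variant"]


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic trial.

    Sampling intervals are given in seconds and converted with ``scales``;
    the defaults mirror a 1000 Hz force / 100 Hz motion-capture recording of
    treadmill running at 2.9 m/s.  ``n_steps`` of a few hundred to a few
    thousand steps corresponds to the several-minute trials of the
    experimental protocol this emulates.
    """

    variant: str = "muscle"
    n_steps: int = 2000
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    gains: Optional[GainSet] = None          # fitted if G is missing
    targets: Optional[dict] = None
    scales: Scales = field(default_factory=Scales)
    dt_force_s: float = 1e-3
    dt_kin_s: float = 1e-2
    meas_noise_force_bw: float = 0.002
    meas_noise_pos: float = 1e-4
    drift_amp_bw: float = 0.0
    drift_period_s: float = 60.0
    drift_shape: str = "linear"   # "linear" ramp over the trial | "sine"
    swing: str = "interpolated"              # "off" | "interpolated"
    swing_lift: float = 0.05
    seed: int = 0
    muscle: Optional[MuscleParams] = None

    def __post_init__(self):
        if self.n_steps < 30:
            raise ValueError("n_steps must be at least 30 for a usable trial")
        if min(self.dt_force_s, self.dt_kin_s) <= 0:
            raise ValueError("sampling intervals must be positive")


@dataclass
class GaitDataset:
    """Dual-rate gait recording, stored nondimensionally with its scales."""

    t_force: np.ndarray
    f_left: np.ndarray      # (n, 3) body weights
    f_right: np.ndarray
    t_kin: np.ndarray
    com: np.ndarray         # (m, 3) leg lengths
    foot_left: np.ndarray
    foot_right: np.ndarray
    scales: Scales
    meta: dict

    def __post_init__(self):
        for t in (self.t_force, self.t_kin):
            if np.any(np.diff(t) <= 0):
                raise ValueError("time channels must be strictly increasing")
        if not (self.t_force[0] <= self.t_kin[0] and self.t_kin[-1] <= self.t_force[-1]):
            raise ValueError("force channels must cover the kinematic span")

    @property
    def dt_force(self) -> float:
        return float(self.t_force[1] - self.t_force[0])

    @property
    def f_total(self) -> np.ndarray:
        return self.f_left + self.f_right


@dataclass
class GroundTruthBundle:
    """What the generator actually did, aligned one-to-one with its steps."""

    gains: GainSet
    noise: NoiseSpec
    nominal: NominalGait
    steps: pd.DataFrame
    fell_at: Optional[int] = None


def _min_jerk(tau):
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def synth_swing_trajectory(
    records: list[StepRecord],
    t_kin: np.ndarray,
    nominal: NominalGait,
    side: str,
    lift: float = 0.05,
    option: str = "interpolated",
) -> np.ndarray:
    """Foot-marker channel for one foot over the trial.

    The foot sits at its anchor during stance.  During swing it follows a
    minimum-jerk path toward a *nominal* advance target (carrying no
    information about the upcoming corrective placement); the actual target
    — with its feedback and noise components — is blended in only during the
    final flight, so early-swing foot state predicts little of the eventual
    placement, as seen in human running.  ``option="off"`` holds the foot at
    its anchors (no swing model).
    """
    own = [r for r in records if r.side == side and r.foot is not None]
    pos = np.zeros((len(t_kin), 3))
    if not own:
        return pos
    stride_dy = 2.0 * nominal.targets["speed"] * nominal.targets["step_period"]
    # before the first stance: hold
    pos[:] = own[0].foot.pos
    for i, r in enumerate(own):
        a0 = r.foot.pos
        in_stance = (t_kin >= r.t_touchdown) & (t_kin <= r.t_takeoff)
        pos[in_stance] = a0
        if i + 1 < len(own):
            r2 = own[i + 1]
            a1 = r2.foot.pos
            sw = (t_kin > r.t_takeoff) & (t_kin < r2.t_touchdown)
            if option == "off":
                pos[sw] = a0
                continue
            t = t_kin[sw]
            tau = (t - r.t_takeoff) / (r2.t_touchdown - r.t_takeoff)
            base_target = a0 + np.array([0.0, stride_dy, 0.0])
            p = a0[None, :] + _min_jerk(tau)[:, None] * (base_target - a0)[None, :]
            p[:, 2] += lift * np.sin(np.pi * np.clip(tau, 0, 1))
            # intermediate (other-side) stance ends at the start of the final
            # flight; only then is the true target blended in
            k = r.index
            mid = next((q for q in records if q.index == k + 1), None)
            t_fl = mid.t_takeoff if mid is not None else r2.t_touchdown
            u = np.clip((t - t_fl) / max(r2.t_touchdown - t_fl, 1e-9), 0.0, 1.0)
            p += _min_jerk(u)[:, None] * (a1 - base_target)[None, :]
            pos[sw] = p
        else:
            pos[t_kin > r.t_takeoff] = a0
    return pos


def _com_series(records: list[StepRecord], t: np.ndarray) -> np.ndarray:
    """COM positions at times ``t`` stitched from flight parabolas and the
    recorded stance trajectories."""
    out = np.full((len(t), 3), np.nan)
    for r in records:
        if r.foot is None:
            continue
        # flight 1: apex_in -> touchdown
        m = (t >= r.apex_in.t) & (t < r.t_touchdown)
        if m.any():
            dt = t[m] - r.apex_in.t
            b = r.apex_in
            out[m, 0] = b.xa + b.vxa * dt
            out[m, 1] = b.ya + b.vya * dt
            out[m, 2] = b.za + b.vza * dt - 0.5 * dt**2
        # stance (interpolate the recorded series)
        m = (t >= r.t_touchdown) & (t <= r.t_takeoff)
        if m.any() and r.state_series.size:
            for j in range(3):
                out[m, j] = np.interp(t[m], r.t_series, r.state_series[:, j])
        # flight 2: takeoff -> apex_out
        if r.apex_out is not None and r.apex_out.t > r.t_takeoff:
            m = (t > r.t_takeoff) & (t < r.apex_out.t)
            if m.any() and r.state_series.size:
                s = r.state_series[-1]
                dt = t[m] - r.t_takeoff
                out[m, 0] = s[0] + s[3] * dt
                out[m, 1] = s[1] + s[4] * dt
                out[m, 2] = s[2] + s[5] * dt - 0.5 * dt**2
    return out


def generate_dataset(
    config: GeneratorConfig,
    nominal: Optional[NominalGait] = None,
    terrain: Optional[Terrain] = None,
    sim: SimConfig = DEFAULT_SIM,
) -> tuple[GaitDataset, GroundTruthBundle]:
    """Run the noisy closed loop and sample it like a laboratory recording.

    Returns the dual-rate dataset and its ground truth.  If the model falls
    before ``n_steps`` the dataset is truncated at the fall (still valid,
    flagged in ``meta['fell']``).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if nominal is None:
        nominal = solve_nominal_gait(cfg.targets, cfg.variant, cfg.muscle)
    gains = cfg.gains or default_gains()
    if gains.G is None:
        gains = fit_force_gains(nominal, gains)
    controller = Controller(nominal, gains)

    records = simulate_run(
        nominal, controller, noise=cfg.noise, terrain=terrain,
        n_steps=cfg.n_steps, rng=rng, config=sim, record_series=True,
    )
    fell_at = records[-1].index if records[-1].fell else None
    used = [r for r in records if r.foot is not None and not r.fell]
    if not used:
        raise RuntimeError("model fell immediately; no usable steps")

    sc = cfg.scales
    dt_f = cfg.dt_force_s / sc.time_s
    dt_k = cfg.dt_kin_s / sc.time_s
    t0 = used[0].apex_in.t
    t1 = used[-1].apex_out.t if used[-1].apex_out is not None else used[-1].t_takeoff
    t_force = t0 + np.arange(0.0, (t1 - t0), dt_f)
    t_kin = t0 + np.arange(0.0, (t1 - t0), dt_k)

    f_left = np.zeros((len(t_force), 3))
    f_right = np.zeros((len(t_force), 3))
    for r in used:
        ch = f_left if r.side == "left" else f_right
        m = (t_force >= r.t_touchdown) & (t_force <= r.t_takeoff)
        for j in range(3):
            ch[m, j] += np.interp(t_force[m], r.t_series, r.grf_series[:, j])

    com = _com_series(used, t_kin)
    # edge samples outside the recorded span: extend nearest values
    for j in range(3):
        col = com[:, j]
        ok = np.isfinite(col)
        com[:, j] = np.interp(t_kin, t_kin[ok], col[ok])
    foot_l = synth_swing_trajectory(used, t_kin, nominal, "left", cfg.swing_lift, cfg.swing)
    foot_r = synth_swing_trajectory(used, t_kin, nominal, "right", cfg.swing_lift, cfg.swing)

    if cfg.drift_amp_bw > 0:
        span = t_force[-1] - t_force[0]
        period = cfg.drift_period_s / sc.time_s
        for ch in (f_left, f_right):
            for j in range(3):
                if cfg.drift_shape == "linear":
                    ch[:, j] += cfg.drift_amp_bw * (
                        (t_force - t_force[0]) / span - 0.5
                    )
                else:
                    ch[:, j] += cfg.drift_amp_bw * np.sin(
                        2 * np.pi * t_force / period + rng.uniform(0, 2 * np.pi)
                    )
    if cfg.meas_noise_force_bw > 0:
        f_left += rng.normal(0, cfg.meas_noise_force_bw, f_left.shape)
        f_right += rng.normal(0, cfg.meas_noise_force_bw, f_right.shape)
    if cfg.meas_noise_pos > 0:
        com += rng.normal(0, cfg.meas_noise_pos, com.shape)
        foot_l += rng.normal(0, cfg.meas_noise_pos, foot_l.shape)
        foot_r += rng.normal(0, cfg.meas_noise_pos, foot_r.shape)

    meta = {
        "mass_kg": sc.mass_kg, "g": sc.g, "leg_length_m": sc.leg_length_m,
        "speed_mps": nominal.targets["speed"] * sc.speed_mps,
        "schema_version": SCHEMA_VERSION, "seed": cfg.seed,
        "variant": cfg.variant, "n_steps": len(used),
        "fell": fell_at is not None,
    }
    ds = GaitDataset(
        t_force=t_force, f_left=f_left, f_right=f_right,
        t_kin=t_kin, com=com, foot_left=foot_l, foot_right=foot_r,
        scales=sc, meta=meta,
    )

    rows = []
    for r in used:
        dev = nominal.canonical_deviation(r.apex_in, r.side)
        rows.append({
            "index": r.index, "side": r.side,
            "dvx_c": dev[0], "dvy_c": dev[1], "dza": dev[2],
            "Px": r.Px, "Py": r.Py, "Pz": r.Pz,
            "rel_foot_x": r.command.rel_foot[0], "rel_foot_y": r.command.rel_foot[1],
            "landing_length": r.command.landing_length,
            "eps": r.command.eps,
            "fp_noise_x": r.command.fp_noise[0], "fp_noise_y": r.command.fp_noise[1],
            "Tstance": r.Tstance, "net_leg_work": r.net_leg_work,
            "apex_t": r.apex_in.t, "t_touchdown": r.t_touchdown,
            "t_takeoff": r.t_takeoff,
        })
    truth = GroundTruthBundle(
        gains=gains, noise=cfg.noise, nominal=nominal,
        steps=pd.DataFrame(rows), fell_at=fell_at,
    )
    return ds, truth


# ---------------------------------------------------------------------------
# on-disk format: forces.tsv + kin.tsv + meta.json, SI units
# ---------------------------------------------------------------------------

def write_dataset(ds: GaitDataset, path) -> None:
    """Write a dataset directory: forces.tsv (N), kin.tsv (m), meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sc = ds.scales
    fdf = pd.DataFrame(
        np.column_stack([
            ds.t_force * sc.time_s,
            ds.f_left * sc.force_n,
            ds.f_right * sc.force_n,
        ]),
        columns=_FORCE_COLS,
    )
    kdf = pd.DataFrame(
        np.column_stack([
            ds.t_kin * sc.time_s,
            ds.com * sc.leg_length_m,
            ds.foot_left * sc.leg_length_m,
            ds.foot_right * sc.leg_length_m,
        ]),
        columns=_KIN_COLS,
    )
    fdf.to_csv(path / "forces.tsv", sep="\t", index=False, float_format="%.17g")
    kdf.to_csv(path / "kin.tsv", sep="\t", index=False, float_format="%.17g")
    with open(path / "meta.json", "w") as fh:
        json.dump(ds.meta, fh, indent=1)


def read_dataset(path) -> GaitDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    for key in _META_KEYS:
        if key not in meta:
            raise ValueError(f"meta.json is missing required key {key!r}")
    if meta["schema_version"] != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema version {meta['schema_version']} "
            f"(expected {SCHEMA_VERSION})"
        )
    fdf = pd.read_csv(path / "forces.tsv", sep="\t")
    kdf = pd.read_csv(path / "kin.tsv", sep="\t")
    for df, cols, name in ((fdf, _FORCE_COLS, "forces.tsv"), (kdf, _KIN_COLS, "kin.tsv")):
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"{name} is missing columns {sorted(missing)}")
    sc = Scales(meta["mass_kg"], meta["g"], meta["leg_length_m"])
    return GaitDataset(
        t_force=fdf["time"].to_numpy() / sc.time_s,
        f_left=fdf[["flx", "fly", "flz"]].to_numpy() / sc.force_n,
        f_right=fdf[["frx", "fry", "frz"]].to_numpy() / sc.force_n,
        t_kin=kdf["time"].to_numpy() / sc.time_s,
        com=kdf[["com_x", "com_y", "com_z"]].to_numpy() / sc.leg_length_m,
        foot_left=kdf[["lfoot_x", "lfoot_y", "lfoot_z"]].to_numpy() / sc.leg_length_m,
        foot_right=kdf[["rfoot_x", "rfoot_y", "rfoot_z"]].to_numpy() / sc.leg_length_m,
        scales=sc,
        meta=meta,
    )


def load_external(path, channel_map: dict, scales: Scales):  # pragma: no cover
    """Stub loader for third-party recordings (e.g. public running datasets).

    Intended use: convert an external file layout into the package schema by
    supplying ``channel_map`` — a mapping from the schema channel names
    (``flx`` ... ``frz``, ``com_x`` ... ``rfoot_z``, ``time``) to columns or
    arrays of the external source — plus the subject's :class:`Scales`.
    Parsing any specific external layout is out of scope for this package;
    adapt the recording to two tables plus metadata and use
    :func:`read_dataset`, or construct :class:`GaitDataset` directly.
    """
    raise NotImplementedError(
        "map the external recording onto the forces/kin/meta schema and use "
        "read_dataset, or build a GaitDataset directly"
    )
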