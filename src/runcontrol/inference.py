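"""The variability-mining pipeline: from gait recordings to control gains.

Given a dual-rate gait recording (per-foot 3D ground reaction forces plus
COM-proxy and foot-marker kinematics), the pipeline

1. reconstructs COM velocities by integrating the mass-normalized net force,
   fixing integration constants by the zero-trial-mean assumption and
   removing drift (force-channel offsets measured from the flight phases,
   then a piecewise-linear detrend of the integrated velocity; a zero-phase
   Butterworth high-pass is available as an alternative);
2. segments stances (vertical GRF threshold), flights, and flight apexes
   (descending zero crossing of vertical velocity, with end-of-stance
   substitution when there is no apex);
3. extracts per-step features — stance impulses, half-stance vertical
   impulses, foot placement relative to the COM at stance start, landing leg
   length, phase-binned GRFs — as deviations from subject/side means;
4. fits the control regressions (impulse, half-impulse, landing-length and
   foot-placement families), the apex-to-apex return maps and their stride
   eigenvalues, phase-dependent GRF sensitivities, predictor power versus
   gait phase, and bootstrap gain distributions versus sample size.

All quantities are nondimensional (see :mod:`runcontrol.states`); impulses
are mass-normalized, i.e. in velocity units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, sosfiltfilt

from .synthetic import GaitDataset

__all__ = [
    "EventTable",
    "StepFeatures",
    "RegressionResult",
    "ApexMapResult",
    "com_kinematics_from_grf",
    "segment_events",
    "extract_step_features",
    "combine_features",
    "fit_control_regressions",
    "reduced_form_regressions",
    "fit_apex_map",
    "phase_sensitivities",
    "predictor_power_vs_phase",
    "bootstrap_gain_vs_n",
    "symmetry_check",
    "analyze",
]

#: stance detection threshold, body weights (~30 N for a 67 kg runner)
FORCE_THRESHOLD = 0.05
N_BINS = 20

_APEX_PREDICTORS = ["dvx", "dvy", "dza"]
_POSITION_PREDICTORS = ["dxa", "dya"]
_OUTPUTS = {
    "impulse_x": "dPx",
    "impulse_y": "dPy",
    "half_impulse_first": "dPz1",
    "half_impulse_second": "dPz2",
    "landing_length": "dll",
    "fp_x": "dfp_x",
    "fp_y": "dfp_y",
}


@dataclass
class EventTable:
    """Per-step gait events: stance bounds, side, and the preceding apex."""

    table: pd.DataFrame  # columns: side, t_td, t_to, t_apex, apex_sub

    def __len__(self):
        return len(self.table)


@dataclass
class StepFeatures:
    """Per-step features and deviations; ``grf_bins`` holds the phase-binned
    GRF (n_steps, N_BINS, 3 components)."""

    table: pd.DataFrame
    grf_bins: np.ndarray
    grf_bins_dev: np.ndarray = None
    n_bins: int = N_BINS

    @property
    def phi(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) / self.n_bins


@dataclass
class RegressionResult:
    """One fitted linear control model."""

    model_id: str
    side: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r2: float
    n: int

    def __repr__(self):
        terms = " + ".join(
            f"{v:+.3f}*{k}" for k, v in self.params.items() if k != "const"
        )
        return (
            f"<{self.model_id} [{self.side}]: {terms}  "
            f"(R2={self.r2:.2f}, n={self.n})>"
        )


@dataclass
class ApexMapResult:
    """Apex-to-apex return maps and stride eigenvalues."""

    K_RL: np.ndarray
    K_LR: np.ndarray
    bse_RL: np.ndarray
    bse_LR: np.ndarray
    significant_RL: np.ndarray
    significant_LR: np.ndarray
    stride_eigenvalues: np.ndarray
    spectral_radius: float
    n_pairs: int


# ---------------------------------------------------------------------------
# kinematics and events
# ---------------------------------------------------------------------------

def _stance_intervals(t: np.ndarray, fz: np.ndarray, threshold: float) -> list[tuple[float, float]]:
    """Contiguous threshold crossings of one foot's vertical force, with
    linear sub-sample refinement of the crossing times."""
    above = fz > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(fz)]
    out = []
    for s, e in zip(starts, ends):
        if e - s < 5:
            continue  # spurious spike
        t0 = t[s]
        if s > 0:
            t0 = np.interp(threshold, [fz[s - 1], fz[s]], [t[s - 1], t[s]])
        t1 = t[e - 1]
        if e < len(fz):
            t1 = np.interp(threshold, [fz[e], fz[e - 1]], [t[e], t[e - 1]])
        out.append((float(t0), float(t1)))
    return out


def com_kinematics_from_grf(
    ds: GaitDataset,
    threshold: float = FORCE_THRESHOLD,
    drift_removal: str = "detrend",
    window_steps: int = 20,
    cutoff_divisor: float = 8.0,
) -> pd.DataFrame:
    """COM velocity deviations on the force clock.

    Mass-normalized accelerations (total GRF minus gravity) are integrated
    once; the integration constants are fixed by zero trial-mean velocity
    and acceleration; the slow integration drift is then removed.

    ``drift_removal`` selects the drift estimator:

    * ``"detrend"`` (default): subtract a piecewise-linear baseline through
      consecutive ``window_steps``-step window means.  This touches only
      timescales far above the step period, so step-scale deviations — the
      signal every control regression uses — pass through essentially
      unattenuated.
    * ``"butterworth"``: zero-phase second-order high-pass with cutoff at
      the mean step frequency divided by ``cutoff_divisor``.  Note that a
      cutoff as high as step frequency / 8 noticeably attenuates the
      near-white apex-deviation sequence and inflates regression slopes;
      it is provided for comparison with that convention.
    * ``"none"``: mean subtraction only.
    """
    t = ds.t_force
    dt = np.diff(t)
    if np.max(dt) > 1.5 * np.min(dt):
        raise ValueError("force channels have gaps; cannot integrate")
    stances = (
        _stance_intervals(t, ds.f_left[:, 2], threshold)
        + _stance_intervals(t, ds.f_right[:, 2], threshold)
    )
    if len(stances) < 10:
        raise ValueError(
            f"trial has only {len(stances)} steps; need at least 10 for the "
            "drift filter to be defined"
        )
    step_freq = len(stances) / (t[-1] - t[0])

    F = ds.f_total.copy()
    F -= _flight_offset_baseline(t, F, sorted(stances))
    a = F
    a[:, 2] -= 1.0
    a -= a.mean(axis=0)
    v = cumulative_trapezoid(a, t, axis=0, initial=0.0)
    v -= v.mean(axis=0)
    if drift_removal == "butterworth":
        fs = 1.0 / float(np.mean(dt))
        sos = butter(2, (step_freq / cutoff_divisor) / (fs / 2.0), "high", output="sos")
        v = sosfiltfilt(sos, v, axis=0)
    elif drift_removal == "detrend":
        v = v - _piecewise_linear_baseline(t, v, window_steps / step_freq)
    elif drift_removal != "none":
        raise ValueError(f"unknown drift_removal {drift_removal!r}")
    return pd.DataFrame({"t": t, "vx": v[:, 0], "vy": v[:, 1], "vz": v[:, 2]})


def _flight_offset_baseline(
    t: np.ndarray, F: np.ndarray, stances: list[tuple[float, float]], shrink: float = 0.15
) -> np.ndarray:
    """Force-channel drift estimated from the flight phases.

    While airborne the true ground reaction force is zero, so the mean
    reading over each flight interval measures the instantaneous channel
    offset; a piecewise-linear interpolant through these per-flight offsets
    tracks slow load-cell drift without touching the stance-phase signal.
    Flight intervals are shrunk by ``shrink`` of their duration at each end
    to stay clear of the detection-threshold tails.
    """
    centers, offsets = [], []
    for (s0, e0), (s1, _) in zip(stances[:-1], stances[1:]):
        a, b = e0, s1
        pad = shrink * (b - a)
        m = (t > a + pad) & (t < b - pad)
        if m.sum() >= 5:
            centers.append(0.5 * (a + b))
            offsets.append(F[m].mean(axis=0))
    if len(centers) < 3:
        return np.zeros_like(F)
    centers = np.asarray(centers)
    offsets = np.asarray(offsets)
    return np.column_stack(
        [np.interp(t, centers, offsets[:, j]) for j in range(F.shape[1])]
    )


def _piecewise_linear_baseline(t: np.ndarray, v: np.ndarray, window: float) -> np.ndarray:
    """Piecewise-linear drift baseline through consecutive window means."""
    n_node = max(int(np.ceil((t[-1] - t[0]) / window)), 2) + 1
    nodes = np.linspace(t[0], t[-1], n_node)
    centers = 0.5 * (nodes[:-1] + nodes[1:])
    base = np.empty_like(v)
    idx = np.searchsorted(nodes, t, side="right") - 1
    idx = np.clip(idx, 0, n_node - 2)
    for j in range(v.shape[1]):
        means = np.array([v[idx == i, j].mean() for i in range(n_node - 1)])
        base[:, j] = np.interp(t, centers, means)
    return base


def segment_events(
    ds: GaitDataset,
    kin: Optional[pd.DataFrame] = None,
    threshold: float = FORCE_THRESHOLD,
) -> EventTable:
    """Detect stances, flights, and flight apexes.

    Stances are where a foot's vertical GRF exceeds the threshold; sides
    must alternate with no double support (running).  The apex preceding
    each stance is the descending zero crossing of the reconstructed
    vertical COM velocity during the flight; if the velocity is already
    negative at takeoff the end-of-stance instant substitutes for the apex.
    The first stance of the trial (no preceding flight) is dropped.
    """
    if kin is None:
        kin = com_kinematics_from_grf(ds, threshold)
    stl = [(s, e, "left") for s, e in _stance_intervals(ds.t_force, ds.f_left[:, 2], threshold)]
    str_ = [(s, e, "right") for s, e in _stance_intervals(ds.t_force, ds.f_right[:, 2], threshold)]
    allst = sorted(stl + str_)
    rows = []
    tv, vz = kin["t"].to_numpy(), kin["vz"].to_numpy()
    for prev, cur in zip(allst[:-1], allst[1:]):
        if cur[2] == prev[2]:
            raise ValueError("consecutive stances on the same side; not alternating running")
        if cur[0] < prev[1]:
            raise ValueError("overlapping stance phases (double support); not running")
        m = (tv > prev[1]) & (tv < cur[0])
        t_apex, sub = prev[1], True
        if m.any():
            vzf = vz[m]
            tf = tv[m]
            idx = np.flatnonzero((vzf[:-1] > 0) & (vzf[1:] <= 0))
            if idx.size:
                i = idx[-1]
                t_apex = float(np.interp(0.0, [vzf[i + 1], vzf[i]], [tf[i + 1], tf[i]]))
                sub = False
        rows.append({
            "side": cur[2], "t_td": cur[0], "t_to": cur[1],
            "t_apex": t_apex, "apex_sub": sub,
        })
    return EventTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# per-step features
# ---------------------------------------------------------------------------

def _interp_cols(tq, t, arr):
    return np.column_stack([np.interp(tq, t, arr[:, j]) for j in range(arr.shape[1])])


def extract_step_features(
    ds: GaitDataset,
    events: Optional[EventTable] = None,
    kin: Optional[pd.DataFrame] = None,
    subject: str = "s0",
    threshold: float = FORCE_THRESHOLD,
) -> StepFeatures:
    """Per-step deviation features from one trial.

    Impulses are trapezoid integrals of the total GRF over stance (vertical
    impulse split at the stance midpoint); foot placement is the foot marker
    minus the COM at touchdown; landing leg length is the COM-to-foot
    distance at touchdown.  Deviations subtract the subject x side mean.
    Steps clipped by the trial edges are dropped.
    """
    if kin is None:
        kin = com_kinematics_from_grf(ds, threshold)
    if events is None:
        events = segment_events(ds, kin, threshold)
    t = ds.t_force
    F = ds.f_total
    cumF = cumulative_trapezoid(F, t, axis=0, initial=0.0)

    def seg_impulse(a, b):
        return _interp_cols([b], t, cumF)[0] - _interp_cols([a], t, cumF)[0]

    tv = kin["t"].to_numpy()
    vxy = kin[["vx", "vy"]].to_numpy()
    tk = ds.t_kin
    rows, bins = [], []
    for _, ev in events.table.iterrows():
        if ev.t_apex < tk[0] or ev.t_to > tk[-1] or ev.t_to > t[-1]:
            continue  # clipped by trial edges
        P = seg_impulse(ev.t_td, ev.t_to)
        mid = 0.5 * (ev.t_td + ev.t_to)
        Pz1 = seg_impulse(ev.t_td, mid)[2]
        v_apex = _interp_cols([ev.t_apex], tv, vxy)[0]
        v_td = _interp_cols([ev.t_td], tv, vxy)[0]
        com_apex = _interp_cols([ev.t_apex], tk, ds.com)[0]
        com_td = _interp_cols([ev.t_td], tk, ds.com)[0]
        foot_ch = ds.foot_left if ev.side == "left" else ds.foot_right
        foot_td = _interp_cols([ev.t_td], tk, foot_ch)[0]
        edges = np.linspace(ev.t_td, ev.t_to, N_BINS + 1)
        ce = _interp_cols(edges, t, cumF)
        bins.append(np.diff(ce, axis=0) / np.diff(edges)[:, None])
        rows.append({
            "subject": subject, "side": ev.side,
            "t_apex": ev.t_apex, "t_td": ev.t_td, "t_to": ev.t_to,
            "Tstance": ev.t_to - ev.t_td, "apex_sub": bool(ev.apex_sub),
            "vx": v_apex[0], "vy": v_apex[1],
            "xa": com_apex[0], "ya": com_apex[1], "za": com_apex[2],
            "vx_td": v_td[0], "vy_td": v_td[1], "z_td": com_td[2],
            "Px": P[0], "Py": P[1], "Pz": P[2],
            "Pz1": Pz1, "Pz2": P[2] - Pz1,
            "fp_x": foot_td[0] - com_td[0], "fp_y": foot_td[1] - com_td[1],
            "ll": float(np.linalg.norm(com_td - foot_td)),
        })
    table = pd.DataFrame(rows).reset_index(drop=True)
    grf_bins = np.array(bins)
    feats = StepFeatures(table=table, grf_bins=grf_bins)
    _add_deviations(feats)
    return feats


def _add_deviations(feats: StepFeatures) -> None:
    """Subject x side mean subtraction for all feature columns and the
    binned GRFs."""
    tb = feats.table
    raw = ["vx", "vy", "za", "xa", "ya", "vx_td", "vy_td", "z_td",
           "Px", "Py", "Pz", "Pz1", "Pz2", "fp_x", "fp_y", "ll", "Tstance"]
    g = tb.groupby(["subject", "side"])
    for c in raw:
        tb["d" + c] = tb[c] - g[c].transform("mean")
    dev = np.empty_like(feats.grf_bins)
    for key, idx in g.indices.items():
        dev[idx] = feats.grf_bins[idx] - feats.grf_bins[idx].mean(axis=0)
    feats.grf_bins_dev = dev


def combine_features(parts: list[StepFeatures]) -> StepFeatures:
    """Pool trials/subjects; deviations are recomputed within each
    subject x side group before pooling."""
    table = pd.concat([p.table for p in parts], ignore_index=True)
    grf = np.concatenate([p.grf_bins for p in parts], axis=0)
    out = StepFeatures(table=table, grf_bins=grf)
    _add_deviations(out)
    return out


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def _ols(y, X: pd.DataFrame, model_id: str, side: str) -> RegressionResult:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        raise ValueError(
            f"rank-deficient design for {model_id} [{side}]: predictors "
            f"{corr.index[i]!r} and {corr.columns[j]!r} are collinear"
        )
    fit = sm.OLS(np.asarray(y), sm.add_constant(X)).fit()
    return RegressionResult(
        model_id=model_id, side=side,
        params=fit.params.drop("const"), bse=fit.bse.drop("const"),
        pvalues=fit.pvalues.drop("const"), r2=float(fit.rsquared), n=int(fit.nobs),
    )


def fit_control_regressions(
    feats: StepFeatures,
    predictor_set: str = "apex",
    outputs: Optional[list[str]] = None,
    min_steps: int = 30,
) -> dict:
    """OLS control models per output family and side.

    ``predictor_set``: ``"apex"`` uses the flight-apex deviations
    (dvx, dvy, dza); ``"apex+position"`` adds the apex horizontal positions
    (the station-keeping check); ``"continuous"`` uses the COM state at the
    start of the current stance instead of the apex state.
    """
    tb = feats.table
    if predictor_set == "apex":
        preds = _APEX_PREDICTORS
    elif predictor_set == "apex+position":
        preds = _APEX_PREDICTORS + _POSITION_PREDICTORS
    elif predictor_set == "continuous":
        # COM state at the start of the current stance instead of the apex
        preds = ["dvx_td", "dvy_td", "dz_td"]
    else:
        raise ValueError(f"unknown predictor_set {predictor_set!r}")
    outputs = outputs or list(_OUTPUTS)
    results: dict = {}
    for side in ("left", "right"):
        sel = tb[tb.side == side]
        if len(sel) < min_steps:
            raise ValueError(f"only {len(sel)} {side} steps; need >= {min_steps}")
        X = sel[preds]
        for fam in outputs:
            results.setdefault(fam, {})[side] = _ols(
                sel[_OUTPUTS[fam]], X, fam, side
            )
    return results


#: reduced predictor sets of the published regression forms
_REDUCED_FORMS = {
    "impulse_x": ("dPx", ["dvx"]),
    "impulse_y": ("dPy", ["dvy"]),
    "half_impulse_first": ("dPz1", ["dza"]),
    "half_impulse_second": ("dPz2", ["dza"]),
    "landing_length": ("dll", ["dza"]),
    "fp_x": ("dfp_x", ["dvx"]),
    "fp_y": ("dfp_y", ["dvy", "dza"]),
}


def reduced_form_regressions(feats: StepFeatures, min_steps: int = 30) -> dict:
    """The published reduced-form control regressions (one or two significant
    predictors per output), fitted per side."""
    tb = feats.table
    results: dict = {}
    for side in ("left", "right"):
        sel = tb[tb.side == side]
        if len(sel) < min_steps:
            raise ValueError(f"only {len(sel)} {side} steps; need >= {min_steps}")
        for fam, (ycol, preds) in _REDUCED_FORMS.items():
            results.setdefault(fam, {})[side] = _ols(sel[ycol], sel[preds], fam, side)
    return results


def fit_apex_map(feats: StepFeatures, min_pairs: int = 30, alpha: float = 0.05) -> ApexMapResult:
    """Per-side 3x3 apex-to-apex maps (Poincare-section Jacobians) and the
    eigenvalues of their stride product."""
    tb = feats.table.reset_index(drop=True)
    Ks, Bs, Ss, ns = {}, {}, {}, {}
    for side_in, key in (("right", "RL"), ("left", "LR")):
        Xr, Yr = [], []
        for i in range(len(tb) - 1):
            a, b = tb.iloc[i], tb.iloc[i + 1]
            if a.side != side_in or b.side == a.side:
                continue
            if a.subject != b.subject or b.t_apex <= a.t_apex:
                continue
            Xr.append([a.dvx, a.dvy, a.dza])
            Yr.append([b.dvx, b.dvy, b.dza])
        if len(Xr) < min_pairs:
            raise ValueError(f"only {len(Xr)} apex pairs for {key}; need >= {min_pairs}")
        X = pd.DataFrame(Xr, columns=_APEX_PREDICTORS)
        Y = np.asarray(Yr)
        K = np.zeros((3, 3))
        B = np.zeros((3, 3))
        S = np.zeros((3, 3), dtype=bool)
        for r in range(3):
            res = _ols(Y[:, r], X, f"apex_map_{key}", side_in)
            K[r] = res.params.to_numpy()
            B[r] = res.bse.to_numpy()
            S[r] = res.pvalues.to_numpy() < alpha
        Ks[key], Bs[key], Ss[key], ns[key] = K, B, S, len(Xr)
    ev = np.linalg.eigvals(Ks["LR"] @ Ks["RL"])
    ev = ev[np.argsort(-np.abs(ev))]
    return ApexMapResult(
        K_RL=Ks["RL"], K_LR=Ks["LR"], bse_RL=Bs["RL"], bse_LR=Bs["LR"],
        significant_RL=Ss["RL"], significant_LR=Ss["LR"],
        stride_eigenvalues=ev, spectral_radius=float(np.max(np.abs(ev))),
        n_pairs=min(ns.values()),
    )


def phase_sensitivities(feats: StepFeatures) -> dict:
    """Phase-dependent GRF sensitivities: 20 OLS fits per GRF component of
    the binned force deviations on the apex-state deviations.

    Returns, per side, ``coef`` (n_bins, 3 components, 3 predictors), the
    standard errors, and per-bin R2 values.
    """
    tb = feats.table
    out = {}
    for side in ("left", "right"):
        m = (tb.side == side).to_numpy()
        X = tb.loc[m, _APEX_PREDICTORS]
        coef = np.zeros((feats.n_bins, 3, 3))
        bse = np.zeros_like(coef)
        r2 = np.zeros((feats.n_bins, 3))
        for j in range(feats.n_bins):
            for c in range(3):
                res = _ols(feats.grf_bins_dev[m, j, c], X, f"grf_phase_{j}_{c}", side)
                coef[j, c] = res.params.to_numpy()
                bse[j, c] = res.bse.to_numpy()
                r2[j, c] = res.r2
        out[side] = {"coef": coef, "bse": bse, "r2": r2, "phi": feats.phi}
    return out


def predictor_power_vs_phase(
    ds: GaitDataset,
    events: Optional[EventTable] = None,
    kin: Optional[pd.DataFrame] = None,
    n_phases: int = N_BINS,
    min_steps: int = 30,
) -> dict:
    """R2 of foot-placement prediction from the COM state versus the swing
    foot state sampled at phases of the previous step.

    One step spans touchdown to touchdown.  COM-based predictors are
    (vx, vy, z); foot-based predictors are the landing foot's position and
    velocity relative to the COM in the placement direction.  Returns
    ``{predictor: {side: {"x": r2[n_phases], "y": ...}}}`` plus the phase
    grid; by construction the foot-based R2 reaches 1 at touchdown.
    """
    if ds.foot_left is None or ds.foot_right is None:
        raise ValueError(
            "foot marker channels are required; generate the dataset with "
            "the swing-trajectory option enabled"
        )
    if kin is None:
        kin = com_kinematics_from_grf(ds)
    if events is None:
        events = segment_events(ds, kin)
    ev = events.table.reset_index(drop=True)
    tk, tv = ds.t_kin, kin["t"].to_numpy()
    vint = kin[["vx", "vy"]].to_numpy()
    dtk = float(tk[1] - tk[0])
    vel_l = np.gradient(ds.foot_left, dtk, axis=0)
    vel_r = np.gradient(ds.foot_right, dtk, axis=0)
    com_v = np.gradient(ds.com, dtk, axis=0)

    recs = {s: {"y_out": {"x": [], "y": []}, "com": [], "foot": []}
            for s in ("left", "right")}
    phases = np.arange(1, n_phases + 1) / n_phases  # last phase = touchdown
    for i in range(1, len(ev)):
        a, b = ev.iloc[i - 1], ev.iloc[i]
        span = b.t_td - a.t_td
        tp = a.t_td + phases * span
        if tp[0] < tk[0] or b.t_td > tk[-1]:
            continue
        side = b.side
        foot = ds.foot_left if side == "left" else ds.foot_right
        fvel = vel_l if side == "left" else vel_r
        com_td = _interp_cols([b.t_td], tk, ds.com)[0]
        foot_td = _interp_cols([b.t_td], tk, foot)[0]
        recs[side]["y_out"]["x"].append(foot_td[0] - com_td[0])
        recs[side]["y_out"]["y"].append(foot_td[1] - com_td[1])
        comst = np.column_stack([
            _interp_cols(tp, tv, vint),           # vx, vy
            _interp_cols(tp, tk, ds.com)[:, 2:3],  # z
        ])
        rel = _interp_cols(tp, tk, foot) - _interp_cols(tp, tk, ds.com)
        relv = _interp_cols(tp, tk, fvel) - _interp_cols(tp, tk, com_v)
        recs[side]["com"].append(comst)
        recs[side]["foot"].append(np.column_stack([rel[:, :2], relv[:, :2]]))

    def _r2(X, y):
        X = np.column_stack([np.ones(len(X)), X])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return 1.0 - resid.var() / y.var()

    out = {"phi": np.arange(1, n_phases + 1) / n_phases, "com": {}, "foot": {}}
    for side, d in recs.items():
        n = len(d["com"])
        if n < min_steps:
            continue
        com_arr = np.array(d["com"])     # (n, phases, 3)
        foot_arr = np.array(d["foot"])   # (n, phases, 4): relx, rely, relvx, relvy
        for pred in ("com", "foot"):
            out[pred][side] = {}
            for direction, ycol in (("x", 0), ("y", 1)):
                y = np.array(d["y_out"][direction])
                y = y - y.mean()
                r2s = np.zeros(n_phases)
                for j in range(n_phases):
                    if pred == "com":
                        X = com_arr[:, j, :]
                    else:
                        X = foot_arr[:, j, [ycol, ycol + 2]]
                    r2s[j] = _r2(X - X.mean(axis=0), y)
                out[pred][side][direction] = r2s
    return out


def bootstrap_gain_vs_n(
    feats: StepFeatures,
    n_strides: list[int],
    n_boot: int = 200,
    rng: Optional[np.random.Generator] = None,
    family: str = "impulse_x",
    side: str = "left",
    resample: bool = True,
) -> dict:
    """Bootstrap distribution of a control gain versus sample size.

    For each ``Nstride``, draws ``n_boot`` resamples of that many strides
    (steps of the chosen side) from the pooled steps and refits the
    reduced-form gain; reports quantiles, standard deviations, and the
    log-log slope of s.d. versus Nstride.  With ``resample=False`` each
    "sample" is the first ``Nstride`` strides (so ``Nstride`` equal to all
    available strides reproduces the full-sample OLS fit exactly).
    """
    rng = rng or np.random.default_rng(0)
    ycol, preds = _REDUCED_FORMS[family]
    if len(preds) != 1:
        raise ValueError("bootstrap scaling is defined for single-predictor forms")
    sel = feats.table[feats.table.side == side]
    x = sel[preds[0]].to_numpy()
    y = sel[ycol].to_numpy()
    n_avail = len(x)
    if max(n_strides) > n_avail:
        raise ValueError(f"Nstride grid exceeds available strides ({n_avail})")
    gains = np.zeros((len(n_strides), n_boot))
    for i, N in enumerate(n_strides):
        if resample:
            idx = rng.integers(0, n_avail, size=(n_boot, N))
        else:
            idx = np.tile(np.arange(N), (n_boot, 1))
        xs, ys = x[idx], y[idx]
        xm = xs - xs.mean(axis=1, keepdims=True)
        ym = ys - ys.mean(axis=1, keepdims=True)
        gains[i] = (xm * ym).sum(axis=1) / (xm * xm).sum(axis=1)
    sd = gains.std(axis=1)
    if len(n_strides) > 1 and np.all(sd > 0):
        slope = float(np.polyfit(np.log(n_strides), np.log(sd), 1)[0])
    else:
        slope = float("nan")  # degenerate grid or resampling disabled
    return {
        "Nstride": np.asarray(n_strides),
        "gains": gains,
        "sd": sd,
        "median": np.median(gains, axis=1),
        "quantiles": np.quantile(gains, [0.25, 0.5, 0.75], axis=1),
        "loglog_slope": slope,
    }


#: axis of each output / predictor, for mirror-parity classification
_AXIS = {
    "impulse_x": "x", "impulse_y": "y", "half_impulse_first": "z",
    "half_impulse_second": "z", "landing_length": "z", "fp_x": "x", "fp_y": "y",
    "dvx": "x", "dvy": "y", "dza": "z", "dxa": "x", "dya": "y",
}


def symmetry_check(regressions: dict, n_se: float = 3.0) -> pd.DataFrame:
    """Classify left/right gain pairs as mirror-consistent or not.

    Gains coupling a sideways variable to a non-sideways one should flip
    sign between sides; like-coupled gains should match.  A pair is
    consistent when the parity-adjusted difference is within ``n_se``
    combined standard errors.
    """
    rows = []
    for fam, sides in regressions.items():
        if "left" not in sides or "right" not in sides:
            continue
        L, R = sides["left"], sides["right"]
        for pred in L.params.index:
            parity = -1.0 if (_AXIS[fam] == "x") != (_AXIS[pred] == "x") else 1.0
            diff = L.params[pred] - parity * R.params[pred]
            se = float(np.hypot(L.bse[pred], R.bse[pred]))
            rows.append({
                "family": fam, "predictor": pred, "parity": parity,
                "gain_left": L.params[pred], "gain_right": R.params[pred],
                "se_combined": se, "difference": diff,
                "consistent": bool(abs(diff) <= n_se * se),
            })
    return pd.DataFrame(rows)


def analyze(ds: GaitDataset, bootstrap: bool = False,
            rng: Optional[np.random.Generator] = None) -> dict:
    """Run the full pipeline on one dataset and collect every statistic the
    package reports (regressions, apex maps, phase curves, symmetry report,
    and optionally the bootstrap sample-size analysis)."""
    kin = com_kinematics_from_grf(ds)
    events = segment_events(ds, kin)
    feats = extract_step_features(ds, events, kin)
    full = fit_control_regressions(feats)
    reduced = reduced_form_regressions(feats)
    station = fit_control_regressions(feats, "apex+position",
                                      outputs=["impulse_x", "impulse_y"])
    amap = fit_apex_map(feats)
    phase = phase_sensitivities(feats)
    power = predictor_power_vs_phase(ds, events, kin)
    sym = symmetry_check(reduced)
    out = {
        "features": feats, "events": events, "kin": kin,
        "regressions": full, "reduced_forms": reduced,
        "station_keeping": station, "apex_map": amap,
        "phase_sensitivities": phase, "predictor_power": power,
        "symmetry": sym,
    }
    if bootstrap:
        n_left = int((feats.table.side == "left").sum())
        grid = [n for n in (50, 100, 200, 400, 800) if n <= n_left]
        out["bootstrap"] = bootstrap_gain_vs_n(feats, grid, rng=rng)
    return out


def summarize(results: dict) -> dict:
    """JSON-serializable run summary of an :func:`analyze` result."""
    reg = results["reduced_forms"]
    amap = results["apex_map"]
    feats = results["features"]

    def one(fam, side):
        r = reg[fam][side]
        return {
            "coef": {k: float(v) for k, v in r.params.items()},
            "se": {k: float(v) for k, v in r.bse.items()},
            "r2": r.r2, "n": r.n,
        }

    return {
        "n_steps": int(len(feats.table)),
        "apex_sd": {
            "vx": float(feats.table.dvx.std()),
            "vy": float(feats.table.dvy.std()),
            "za": float(feats.table.dza.std()),
        },
        "regressions": {
            fam: {side: one(fam, side) for side in reg[fam]} for fam in reg
        },
        "apex_map": {
            "K_RL": amap.K_RL.tolist(),
            "K_LR": amap.K_LR.tolist(),
            "stride_eigenvalue_moduli": np.abs(amap.stride_eigenvalues).tolist(),
            "spectral_radius": amap.spectral_radius,
        },
        "symmetry_consistent": bool(results["symmetry"].consistent.all()),
    }
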