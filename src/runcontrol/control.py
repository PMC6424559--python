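"""Nominal periodic gait synthesis and the human-derived feedback controller.

The running motion is parameterized by stance and flight durations, 2D foot
placement, the 3D stance initial condition, and a two-term sine series for
the leg force (direct-force variant) or muscle activation (muscle variant),

    u(t) = A1 sin(2 pi t / (2 Tstance)) + A2 sin(2 pi t / Tstance),

whose second term lets the profile peak off mid-stance.  The nominal gait is
the periodic, left-right mirror-symmetric solution matching target forward
speed, step period, step width and peak leg force, with landing leg length
fixed at 95% of maximum.

Feedback acts once per step, at flight apex, on the deviations
(dvx_a, dvy_a, dz_a) of the apex state from nominal:

* foot placement relative to the COM (sideways gain 0.95, fore-aft gains
  0.42 and -0.76) — step in the direction of the fall;
* landing leg length (gain 0.3 on apex height);
* the force/activation coefficients, dA = G (dvx_a, dvy_a, dz_a), with G
  fitted so the model's one-step apex-return map matches the map measured
  from human treadmill running.

All gains are expressed in a side-canonical frame (left stance); right-stance
behavior follows by mirror symmetry about the sagittal plane (conjugation by
diag(-1, 1, 1)), so cross-coupled sideways gains flip sign between sides.
"""

from __future__ import annotations

import importlib.resources as _res
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .muscle import MTU, MuscleParams
from .simulate import DEFAULT_SIM, SimConfig, simulate_run
from .states import ApexState, MIRROR

__all__ = [
    "DEFAULT_TARGETS",
    "NominalGait",
    "GainSet",
    "ControlCommand",
    "NoiseSpec",
    "Controller",
    "control_waveform",
    "solve_nominal_gait",
    "feedback_foot_placement",
    "feedback_landing_length",
    "feedback_force",
    "fit_force_gains",
    "apply_noise",
    "nominal_command",
    "stride_jacobian",
    "perturbation_remaining",
    "default_gains",
]

#: Nominal gait targets, nondimensional.  These correspond to treadmill
#: running at 2.9 m/s with a 1.05 m leg and a 0.40 s step period; the width
#: is a typical small running step width.  Config values, not claims.
DEFAULT_TARGETS = {
    "speed": 0.9037,
    "step_period": 1.2232,
    "step_width": 0.08,
    "peak_force": 2.5,
}

_M3 = np.diag(MIRROR)  # sagittal mirror on (x, y, z) triples


def control_waveform(t, A1: float, A2: float, Tstance: float):
    """Two-term sine series A1 sin(pi t / Tstance) + A2 sin(2 pi t / Tstance),
    with ``t`` clamped to [0, Tstance] (zero value at both ends)."""
    t = np.clip(np.asarray(t, dtype=float), 0.0, Tstance)
    out = A1 * np.sin(np.pi * t / Tstance) + A2 * np.sin(2.0 * np.pi * t / Tstance)
    return float(out) if out.ndim == 0 else out


@dataclass
class NominalGait:
    """A periodic, mirror-symmetric running gait (canonical left stance).

    Positions are COM relative to the stance foot; ``*_to`` fields are the
    takeoff (end-of-stance) state.  ``residual`` is the maximum constraint
    violation of the periodicity/target system at the solution.
    """

    variant: str
    Tstance: float
    Tflight: float
    A1: float
    A2: float
    x0: float
    y0: float
    z0: float
    vx0: float
    vy0: float
    vz0: float
    landing_length: float = 0.95
    targets: dict = field(default_factory=lambda: dict(DEFAULT_TARGETS))
    residual: float = np.nan
    peak_force: float = np.nan
    # takeoff state (filled by the solver)
    x_to: float = np.nan
    y_to: float = np.nan
    z_to: float = np.nan
    vx_to: float = np.nan
    vy_to: float = np.nan
    vz_to: float = np.nan
    muscle: Optional[MuscleParams] = None

    # -- derived nominal quantities -------------------------------------
    @property
    def apex_height(self) -> float:
        return self.z_to + 0.5 * self.vz_to**2

    def apex_velocity(self, side: str) -> tuple[float, float]:
        """Nominal apex velocity before a stance of ``side``.  The apex
        before a left stance follows a right stance, whose takeoff is the
        mirror of the canonical (left) takeoff."""
        s = 1.0 if side == "left" else -1.0
        return (-s * self.vx_to, self.vy_to)

    def apex_state(self, side: str, xa: float = 0.0, ya: float = 0.0) -> ApexState:
        vxa, vya = self.apex_velocity(side)
        return ApexState(xa=xa, ya=ya, za=self.apex_height, vxa=vxa, vya=vya, side=side)

    def rel_placement(self, side: str) -> tuple[float, float]:
        """Nominal foot-minus-COM offset at touchdown for ``side``."""
        s = 1.0 if side == "left" else -1.0
        return (-s * self.x0, -self.y0)

    def canonical_deviation(self, apex: ApexState, side: str) -> np.ndarray:
        """(dvx, dvy, dz) of an apex state, mirrored into the left-canonical
        frame for the stance of ``side`` that follows it."""
        s = 1.0 if side == "left" else -1.0
        vxa_nom, vya_nom = self.apex_velocity("left")
        return np.array(
            [s * apex.vxa - vxa_nom, apex.vya - vya_nom, apex.za - self.apex_height]
        )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in self.__dict__.items()
            if k not in ("muscle", "targets")
        }
        d["targets"] = {k: float(v) for k, v in self.targets.items()}
        if self.muscle is not None:
            d["muscle"] = {k: float(v) for k, v in self.muscle.__dict__.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NominalGait":
        d = dict(d)
        if d.get("muscle") is not None:
            d["muscle"] = MuscleParams(**d["muscle"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "NominalGait":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GainSet:
    """All controller coefficients, in the left-canonical frame.

    ``K_target`` is the measured right-to-left apex-return map (rows/columns
    ordered vx, vy, z); ``K_significant`` flags entries distinguishable from
    zero.  ``G`` (2x3) maps canonical apex deviations to (dA1, dA2) and is
    model-specific (fitted by :func:`fit_force_gains`).
    """

    fp_vx: float = 0.95
    fp_vy: float = 0.42
    fp_za: float = -0.76
    ll_za: float = 0.3
    K_target: np.ndarray = field(
        default_factory=lambda: np.array(
            [[-0.05, -0.02, 0.31], [-0.08, 0.27, -0.15], [0.02, 0.06, 0.46]]
        )
    )
    K_significant: np.ndarray = field(
        default_factory=lambda: np.array(
            [[False, False, False], [False, True, True], [False, True, True]]
        )
    )
    zero_nonsignificant: bool = False
    G: Optional[np.ndarray] = None
    fit_info: dict = field(default_factory=dict)

    @property
    def K_effective(self) -> np.ndarray:
        K = np.array(self.K_target, dtype=float)
        if self.zero_nonsignificant:
            K = K * np.asarray(self.K_significant)
        return K

    @property
    def K_RL(self) -> np.ndarray:
        """Right-to-left one-step map (lab frame)."""
        return self.K_effective

    @property
    def K_LR(self) -> np.ndarray:
        """Left-to-right map: mirror conjugate of K_RL."""
        return _M3 @ self.K_effective @ _M3

    @property
    def K_canonical(self) -> np.ndarray:
        """One-step map in the side-canonical frame (same for both sides)."""
        return self.K_effective @ _M3

    def stride_eigenvalues(self) -> np.ndarray:
        ev = np.linalg.eigvals(self.K_LR @ self.K_RL)
        return ev[np.argsort(-np.abs(ev))]

    def to_dict(self) -> dict:
        return {
            "fp_vx": self.fp_vx, "fp_vy": self.fp_vy, "fp_za": self.fp_za,
            "ll_za": self.ll_za,
            "K_target": np.asarray(self.K_target).tolist(),
            "K_significant": np.asarray(self.K_significant).astype(bool).tolist(),
            "zero_nonsignificant": self.zero_nonsignificant,
            "G": None if self.G is None else np.asarray(self.G).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GainSet":
        d = dict(d)
        d.pop("reference", None)
        d["K_target"] = np.array(d["K_target"], dtype=float)
        d["K_significant"] = np.array(d["K_significant"], dtype=bool)
        if d.get("G") is not None:
            d["G"] = np.array(d["G"], dtype=float)
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "GainSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_gains() -> GainSet:
    """The packaged human-derived gain set (left-stance values of the
    published regressions, with the measured apex-return map)."""
    with _res.files("runcontrol").joinpath("data/human_gains.yaml").open() as fh:
        return GainSet.from_dict(yaml.safe_load(fh))


@dataclass
class ControlCommand:
    """The control actions chosen at one flight apex for the next stance."""

    side: str
    rel_foot: tuple[float, float]       # commanded (xf - xs, yf - ys), lab frame
    landing_length: float
    A1: float
    A2: float
    Tstance: float
    variant: str = "force"
    muscle: Optional[MuscleParams] = None
    eps: float = 0.0                    # multiplicative profile noise, one per stance
    fp_noise: tuple[float, float] = (0.0, 0.0)  # canonical-frame placement noise

    def profile(self, t):
        """Realized (noise-corrupted, rectified) force or activation profile."""
        u = control_waveform(t, self.A1, self.A2, self.Tstance) * (1.0 + self.eps)
        return np.clip(u, 0.0, None)

    def force_fn(self):
        """Scalar leg force as a function of (t, leg length, leg length rate)."""
        if self.variant == "force":
            return lambda t, l, ldot: float(self.profile(t))
        mtu = MTU(self.muscle or MuscleParams())
        return lambda t, l, ldot: mtu.leg_force(float(self.profile(t)), l, ldot)


@dataclass(frozen=True)
class NoiseSpec:
    """Motor noise: one multiplicative draw per stance on the whole
    force/activation profile, plus additive foot-placement offsets.

    Defaults are calibrated so the simulated apex vertical-position s.d. is
    of order 0.005 (nondimensional, i.e. ~5 mm on a 1.05 m leg) and the
    foot-placement regressions have R^2 of the order seen in human data.
    """

    sd_eps: float = 0.010
    sd_fp_x: float = 0.006
    sd_fp_y: float = 0.007

    def __post_init__(self):
        if min(self.sd_eps, self.sd_fp_x, self.sd_fp_y) < 0:
            raise ValueError("noise standard deviations must be non-negative")


# ---------------------------------------------------------------------------
# feedback laws (Eq-style linear gains, canonical frame)
# ---------------------------------------------------------------------------

def feedback_foot_placement(dev, side: str, gains: GainSet) -> tuple[float, float]:
    """Foot-placement offsets (d(xf-xs), d(yf-ys)) in the lab frame for a
    canonical apex deviation ``dev = (dvx, dvy, dz)``."""
    s = 1.0 if side == "left" else -1.0
    dx_c = gains.fp_vx * dev[0]
    dy = gains.fp_vy * dev[1] + gains.fp_za * dev[2]
    return (s * dx_c, dy)


def feedback_landing_length(dza: float, gains: GainSet = GainSet()) -> float:
    """Landing leg length modulation: 0.3 per unit apex-height deviation."""
    return gains.ll_za * dza


def feedback_force(dev, G: np.ndarray) -> tuple[float, float]:
    """Sine-series coefficient modifications (dA1, dA2) = G . dev."""
    dA = np.asarray(G, dtype=float) @ np.asarray(dev, dtype=float)
    return float(dA[0]), float(dA[1])


class Controller:
    """Human-derived once-per-apex feedback controller."""

    def __init__(self, nominal: NominalGait, gains: Optional[GainSet] = None,
                 enable_force_feedback: bool = True,
                 dA_extra: tuple[float, float] = (0.0, 0.0)):
        self.nominal = nominal
        self.gains = gains or default_gains()
        self.enable_force_feedback = enable_force_feedback
        self.dA_extra = dA_extra

    def command(self, apex: ApexState, side: str) -> ControlCommand:
        nom = self.nominal
        dev = nom.canonical_deviation(apex, side)
        dxf, dyf = feedback_foot_placement(dev, side, self.gains)
        dll = feedback_landing_length(dev[2], self.gains)
        if self.enable_force_feedback and self.gains.G is not None:
            dA1, dA2 = feedback_force(dev, self.gains.G)
        else:
            dA1, dA2 = 0.0, 0.0
        rx_nom, ry_nom = nom.rel_placement(side)
        return ControlCommand(
            side=side,
            rel_foot=(rx_nom + dxf, ry_nom + dyf),
            landing_length=float(np.clip(nom.landing_length + dll, 0.2, 1.0)),
            A1=nom.A1 + dA1 + self.dA_extra[0],
            A2=nom.A2 + dA2 + self.dA_extra[1],
            Tstance=nom.Tstance,
            variant=nom.variant,
            muscle=nom.muscle,
        )


def nominal_command(nominal: NominalGait, side: str) -> ControlCommand:
    """Purely feedforward command (controller off)."""
    rx, ry = nominal.rel_placement(side)
    return ControlCommand(
        side=side, rel_foot=(rx, ry), landing_length=nominal.landing_length,
        A1=nominal.A1, A2=nominal.A2, Tstance=nominal.Tstance,
        variant=nominal.variant, muscle=nominal.muscle,
    )


def apply_noise(cmd: ControlCommand, noise: NoiseSpec,
                rng: np.random.Generator) -> ControlCommand:
    """Corrupt a command with motor noise.

    One multiplicative epsilon per stance scales the whole force/activation
    profile (rectification is re-applied when the profile is evaluated);
    independent Gaussian offsets perturb the commanded foot placement, drawn
    in the canonical frame and mirrored onto the stance side.
    """
    eps = rng.normal(0.0, noise.sd_eps) if noise.sd_eps > 0 else 0.0
    nx = rng.normal(0.0, noise.sd_fp_x) if noise.sd_fp_x > 0 else 0.0
    ny = rng.normal(0.0, noise.sd_fp_y) if noise.sd_fp_y > 0 else 0.0
    s = 1.0 if cmd.side == "left" else -1.0
    return replace(
        cmd,
        rel_foot=(cmd.rel_foot[0] + s * nx, cmd.rel_foot[1] + ny),
        eps=eps,
        fp_noise=(nx, ny),
    )


# ---------------------------------------------------------------------------
# nominal gait synthesis
# ---------------------------------------------------------------------------

def _stance_solution(u, variant, muscle, rtol=1e-11, atol=1e-13):
    """Integrate one stance over [0, Tstance] from the packed unknowns."""
    x0, y0, z0, vx0, vy0, vz0, Ts, Tf, A1, A2 = u
    if variant == "force":
        def force(t, l, ldot):
            return max(control_waveform(t, A1, A2, Ts), 0.0)
    else:
        mtu = MTU(muscle)

        def force(t, l, ldot):
            a = max(control_waveform(t, A1, A2, Ts), 0.0)
            return mtu.leg_force(a, l, ldot)

    def rhs(t, y):
        p = y[0:3]
        l = np.sqrt(p @ p)
        v = y[3:6]
        F = force(t, l, (p @ v) / l)
        up = p / l
        return np.array([v[0], v[1], v[2], F * up[0], F * up[1], F * up[2] - 1.0])

    sol = solve_ivp(rhs, (0.0, Ts), np.array([x0, y0, z0, vx0, vy0, vz0]),
                    method="DOP853", rtol=rtol, atol=atol, dense_output=True)
    return sol, force


def _peak_force(sol, force, Ts, n=600):
    ts = np.linspace(0.0, Ts, n)
    ys = sol.sol(ts)
    p = ys[0:3]
    l = np.sqrt((p * p).sum(axis=0))
    ldot = (p * ys[3:6]).sum(axis=0) / l
    F = np.array([force(t, li, ld) for t, li, ld in zip(ts, l, ldot)])
    i = int(np.argmax(F))
    if 0 < i < n - 1:  # local parabola through the three samples around the max
        f0, f1, f2 = F[i - 1], F[i], F[i + 1]
        denom = f0 - 2 * f1 + f2
        if denom < 0:
            return float(f1 - 0.125 * (f2 - f0) ** 2 / denom)
    return float(F[i])


def solve_nominal_gait(
    targets: Optional[dict] = None,
    variant: str = "force",
    muscle: Optional[MuscleParams] = None,
    landing_length: float = 0.95,
    initial_guess: Optional[np.ndarray] = None,
    tol: float = 1e-6,
) -> NominalGait:
    """Solve for the periodic mirror-symmetric gait matching the targets.

    Unknowns: stance initial COM position/velocity relative to the foot,
    stance and flight durations, and the sine-series coefficients.  The ten
    constraints are: landing leg length; takeoff at maximum leg length;
    mirror periodicity of the post-flight state (z and all velocities);
    forward speed; step width; peak leg force; step period.  Raises if the
    residual cannot be driven below ``tol``.
    """
    tg = dict(DEFAULT_TARGETS)
    if targets:
        tg.update(targets)
    if tg["peak_force"] <= 1.0:
        raise ValueError("peak leg force must exceed one body weight")
    if variant not in ("force", "muscle"):
        raise ValueError(f"unknown model variant {variant!r}")
    if variant == "muscle" and muscle is None:
        muscle = MuscleParams()

    ll = landing_length

    def residual(u):
        x0, y0, z0, vx0, vy0, vz0, Ts, Tf, A1, A2 = u
        sol, force = _stance_solution(u, variant, muscle)
        xe, ye, ze, vxe, vye, vze = sol.sol(Ts)
        le = np.sqrt(xe * xe + ye * ye + ze * ze)
        return np.array([
            np.sqrt(x0 * x0 + y0 * y0 + z0 * z0) - ll,
            le - 1.0,
            vxe + vx0,
            vye - vy0,
            (vze - Tf) - vz0,
            (ze + vze * Tf - 0.5 * Tf * Tf) - z0,
            (ye + vye * Tf - y0) - tg["speed"] * (Ts + Tf),
            (xe + x0) - tg["step_width"],
            _peak_force(sol, force, Ts) - tg["peak_force"],
            (Ts + Tf) - tg["step_period"],
        ])

    if initial_guess is not None:
        u0 = np.asarray(initial_guess, dtype=float)
    elif variant == "force":
        u0 = np.array([0.04, -0.28, 0.9068, -0.02, 0.90, -0.21, 0.80, 0.42, 2.5, -0.1])
    else:
        u0 = np.array([0.04, -0.28, 0.9068, -0.02, 0.90, -0.21, 0.80, 0.42, 0.55, -0.02])

    lb = np.array([-0.3, -0.6, 0.5, -0.5, 0.3, -0.8, 0.3, 0.05, 0.0, -2.0])
    ub = np.array([0.3, 0.1, 0.95, 0.5, 1.5, 0.2, 1.1, 0.9, 5.0, 2.0])
    res = least_squares(residual, u0, bounds=(lb, ub), xtol=3e-16, ftol=3e-16,
                        gtol=1e-15, x_scale="jac", max_nfev=400)
    rmax = float(np.max(np.abs(res.fun)))
    if rmax > tol:
        raise RuntimeError(
            f"nominal gait solver did not converge (max residual {rmax:.2e}); "
            f"residuals: {np.array2string(res.fun, precision=2)}"
        )
    u = res.x
    sol, force = _stance_solution(u, variant, muscle)
    xe, ye, ze, vxe, vye, vze = sol.sol(u[6])
    return NominalGait(
        variant=variant,
        Tstance=float(u[6]), Tflight=float(u[7]), A1=float(u[8]), A2=float(u[9]),
        x0=float(u[0]), y0=float(u[1]), z0=float(u[2]),
        vx0=float(u[3]), vy0=float(u[4]), vz0=float(u[5]),
        landing_length=ll, targets=tg, residual=rmax,
        peak_force=float(_peak_force(sol, force, u[6])),
        x_to=float(xe), y_to=float(ye), z_to=float(ze),
        vx_to=float(vxe), vy_to=float(vye), vz_to=float(vze),
        muscle=muscle,
    )


# ---------------------------------------------------------------------------
# apex-return maps and force-gain fitting
# ---------------------------------------------------------------------------

def one_step_deviation_map(
    nominal: NominalGait,
    controller: Optional[Controller],
    dev: np.ndarray,
    config: SimConfig = DEFAULT_SIM,
) -> np.ndarray:
    """Propagate a canonical apex deviation through one step; return the
    canonical deviation at the next apex."""
    apex = nominal.apex_state("left")
    apex = ApexState(
        xa=apex.xa, ya=apex.ya, za=apex.za + dev[2],
        vxa=apex.vxa + dev[0], vya=apex.vya + dev[1], side="left",
    )
    recs = simulate_run(nominal, controller, n_steps=1, config=config,
                        record_series=False, initial_apex=apex)
    rec = recs[0]
    if rec.fell or rec.apex_out is None:
        raise RuntimeError(
            "runner fell while evaluating the one-step map; "
            "try a smaller perturbation"
        )
    return nominal.canonical_deviation(rec.apex_out, "right")


def finite_difference_step_map(
    nominal: NominalGait,
    controller: Optional[Controller],
    h: float = 1e-4,
    config: SimConfig = DEFAULT_SIM,
) -> np.ndarray:
    """Central finite-difference 3x3 one-step apex map (canonical frame)."""
    K = np.zeros((3, 3))
    for j in range(3):
        e = np.zeros(3)
        e[j] = h
        fp = one_step_deviation_map(nominal, controller, e, config)
        fm = one_step_deviation_map(nominal, controller, -e, config)
        K[:, j] = (fp - fm) / (2.0 * h)
    return K


def fit_force_gains(
    nominal: NominalGait,
    gains: Optional[GainSet] = None,
    h_dev: float = 1e-4,
    h_A: float = 1e-3,
    n_iter: int = 2,
    config: SimConfig = DEFAULT_SIM,
) -> GainSet:
    """Fit the force/activation feedback gains G to the measured apex map.

    With foot-placement and landing-length feedback fixed at their measured
    values, the one-step map is linear in G through the sensitivity B of the
    next apex to (A1, A2): K(G) = K0 + B G.  G minimizes the Frobenius
    mismatch to the target map (iterated linear least squares to absorb the
    mild nonlinearity).  Raises if the fitted closed loop is not stable.
    """
    gains = gains or default_gains()
    K_target = gains.K_canonical

    # sensitivity of the next canonical apex deviation to the A coefficients
    B = np.zeros((3, 2))
    for j in range(2):
        dA = np.zeros(2)
        dA[j] = h_A
        cp = Controller(nominal, replace_G(gains, None), dA_extra=tuple(dA))
        cm = Controller(nominal, replace_G(gains, None), dA_extra=tuple(-dA))
        fp = one_step_deviation_map(nominal, cp, np.zeros(3), config)
        fm = one_step_deviation_map(nominal, cm, np.zeros(3), config)
        B[:, j] = (fp - fm) / (2.0 * h_A)

    G = np.zeros((2, 3))
    for _ in range(n_iter):
        ctrl = Controller(nominal, replace_G(gains, G))
        K_cur = finite_difference_step_map(nominal, ctrl, h_dev, config)
        dG, *_ = np.linalg.lstsq(B, K_target - K_cur, rcond=None)
        G = G + dG
        if np.max(np.abs(dG)) < 1e-10:
            break

    fitted = replace_G(gains, G)
    ctrl = Controller(nominal, fitted)
    K_ach = finite_difference_step_map(nominal, ctrl, h_dev, config)
    ev = np.linalg.eigvals(K_ach @ K_ach)
    radius = float(np.max(np.abs(ev)))
    if radius >= 1.0:
        raise RuntimeError(
            f"fitted closed loop is unstable (stride spectral radius {radius:.3f})"
        )
    fitted.fit_info = {
        "K_achieved_canonical": K_ach,
        "mismatch_fro": float(np.linalg.norm(K_ach - K_target)),
        "stride_spectral_radius": radius,
        "B": B,
    }
    return fitted


def replace_G(gains: GainSet, G) -> GainSet:
    out = GainSet(
        fp_vx=gains.fp_vx, fp_vy=gains.fp_vy, fp_za=gains.fp_za, ll_za=gains.ll_za,
        K_target=np.array(gains.K_target), K_significant=np.array(gains.K_significant),
        zero_nonsignificant=gains.zero_nonsignificant,
        G=None if G is None else np.array(G),
    )
    return out


def stride_jacobian(
    nominal: NominalGait,
    controller: Optional[Controller],
    h: float = 1e-4,
    config: SimConfig = DEFAULT_SIM,
) -> dict:
    """Finite-difference apex-return maps and stride (two-step) eigenvalues.

    Returns the canonical one-step map, the lab-frame per-side maps, and the
    stride-product eigenvalues sorted by modulus (descending).
    """
    Kc = finite_difference_step_map(nominal, controller, h, config)
    K_LR = _M3 @ Kc          # lab frame: left-apex -> right-apex
    K_RL = Kc @ _M3
    ev = np.linalg.eigvals(Kc @ Kc)
    order = np.argsort(-np.abs(ev))
    return {
        "K_canonical": Kc,
        "K_LR": K_LR,
        "K_RL": K_RL,
        "stride_eigenvalues": ev[order],
        "spectral_radius": float(np.max(np.abs(ev))),
    }


def perturbation_remaining(correction_per_step: float, n_steps: int) -> float:
    """Fraction of a deviation remaining after ``n_steps`` when a fraction
    ``correction_per_step`` is corrected each step: (1 - c)**n."""
    return (1.0 - correction_per_step) ** n_steps
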