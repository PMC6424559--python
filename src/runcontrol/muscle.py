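"""Hill-type muscle-tendon unit (MTU) producing the scalar leg force.

The muscle-control model variant drives the leg with a single lumped
extensor-like MTU: an active contractile element (CE) with force-length and
(linear) force-velocity relations, a linear series elastic element (the
tendon) and a linear parallel elastic element.  The CE force is
``F_CE = a * Fiso * psi_v * psi_l``.

Geometry.  A kneed leg is abstracted into an affine map between leg length
and MTU length, ``l_mtu = beta - alpha * l_leg`` with ``alpha > 0``: when the
leg compresses the extensor MTU *lengthens*, so the force-velocity relation
resists rapid compression (damping along the leg axis) — the intrinsic
stabilizing muscle property exploited by the noisy-running results.  By
virtual work the leg force is ``alpha`` times the tendon force.

The force balance of the massless MTU is solved quasistatically: at each
instant the CE length ``lm`` satisfies

    F_SE(l_mtu - lm) = a * Fiso * psi_l(lm) * psi_v(s) + F_PE(lm)

with the CE shortening rate ``s`` tied to the MTU rate (tendon stretch rate
treated as zero at the equilibrium point).  All parameter values are package
defaults chosen for a plausible human-scale gait, not measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["MuscleParams", "MuscleState", "force_length", "force_velocity", "mtu_force", "MTU"]


@dataclass(frozen=True)
class MuscleParams:
    """Parameters of the lumped MTU (nondimensional: forces in body weights,
    lengths in maximum leg lengths)."""

    Fiso: float = 6.0          # max isometric CE force
    l_opt: float = 0.55        # optimal CE length
    w: float = 0.5             # force-length width (fraction of l_opt)
    vmax: float = 2.0          # max CE shortening rate
    k_se: float = 80.0         # tendon stiffness
    se_slack: float = 0.15     # tendon slack length
    k_pe: float = 5.0          # parallel-element stiffness
    pe_slack: float = 0.55     # parallel-element slack length
    f_ecc: float = 1.5         # eccentric force-velocity cap
    alpha: float = 1.0         # leg->MTU affine map: l_mtu = beta - alpha*l_leg
    beta: float = 1.6

    def __post_init__(self):
        if min(self.Fiso, self.vmax, self.k_se, self.k_pe, self.w, self.alpha) <= 0:
            raise ValueError("Fiso, vmax, stiffnesses, w and alpha must be positive")

    def mtu_length(self, l_leg: float) -> float:
        return self.beta - self.alpha * l_leg

    def mtu_rate(self, l_leg_rate: float) -> float:
        return -self.alpha * l_leg_rate


@dataclass
class MuscleState:
    """CE length and (rectified) activation."""

    lm: float
    a: float

    def __post_init__(self):
        if self.lm <= 0:
            raise ValueError("contractile element length must be positive")
        self.a = max(self.a, 0.0)


def force_length(lm, params: MuscleParams = MuscleParams()):
    """Gaussian force-length factor, 1 at the optimum, symmetric in
    relative length deviation: exp(-((lm - l_opt) / (w l_opt))^2)."""
    lm = np.asarray(lm, dtype=float)
    if np.any(lm <= 0):
        raise ValueError("lm must be positive")
    rel = (lm - params.l_opt) / (params.w * params.l_opt)
    out = np.exp(-rel * rel)
    return float(out) if out.ndim == 0 else out


def force_velocity(shortening_rate, params: MuscleParams = MuscleParams()):
    """Linear force-velocity factor, shortening positive.

    1 when isometric, 0 at the maximum shortening rate, capped at ``f_ecc``
    under lengthening.
    """
    s = np.asarray(shortening_rate, dtype=float)
    out = np.clip(1.0 - s / params.vmax, 0.0, params.f_ecc)
    return float(out) if out.ndim == 0 else out


def _pe_force(lm: float, p: MuscleParams) -> float:
    return p.k_pe * max(lm - p.pe_slack, 0.0)


def _se_force(stretch: float, p: MuscleParams) -> float:
    return p.k_se * max(stretch, 0.0)


def mtu_force(
    a: float,
    l_mtu: float,
    l_mtu_dot: float = 0.0,
    params: MuscleParams = MuscleParams(),
    lm_guess: float | None = None,
) -> float:
    """Tendon force of the MTU at activation ``a``, length ``l_mtu`` and
    lengthening rate ``l_mtu_dot`` (quasistatic force balance).

    Returns a non-negative force (body weights, per unit ``alpha`` of the
    leg map; multiply by ``params.alpha`` for the leg force).
    """
    p = params
    a = max(float(a), 0.0)
    lm_max = l_mtu - p.se_slack  # tendon at slack: zero force
    if lm_max <= 1e-9:
        return 0.0
    s = -l_mtu_dot  # CE shortening rate at quasistatic equilibrium
    psi_v = force_velocity(s, p)

    def balance(lm: float) -> float:
        return (
            _se_force(l_mtu - lm - p.se_slack, p)
            - a * p.Fiso * force_length(lm, p) * psi_v
            - _pe_force(lm, p)
        )

    lo = 1e-9
    if balance(lm_max) >= 0.0:
        # equilibrium sits at (or beyond) the slack-tendon boundary: no force
        return 0.0
    if balance(lo) <= 0.0:
        # active force exceeds tendon capacity even at vanishing CE length;
        # parameters are infeasible for this configuration
        raise ValueError(
            f"no MTU equilibrium in (0, {lm_max:.4f}] for a={a}, l_mtu={l_mtu}"
        )
    if lm_guess is not None and lo < lm_guess < lm_max:
        # warm-started Newton; cheap secant fallback to brentq
        lm = lm_guess
        for _ in range(30):
            f = balance(lm)
            h = 1e-8
            df = (balance(min(lm + h, lm_max)) - f) / h
            if df == 0:
                break
            step = f / df
            lm_new = lm - step
            if not (lo < lm_new < lm_max):
                break
            if abs(step) < 1e-12:
                return max(_se_force(l_mtu - lm_new - p.se_slack, p), 0.0)
            lm = lm_new
    lm = brentq(balance, lo, lm_max, xtol=1e-13, rtol=8.9e-16)
    return max(_se_force(l_mtu - lm - p.se_slack, p), 0.0)


class MTU:
    """Stateful wrapper caching the last CE-length solution for fast
    repeated calls inside the stance integrator."""

    def __init__(self, params: MuscleParams = MuscleParams()):
        self.params = params
        self._lm = params.l_opt

    def leg_force(self, a: float, l_leg: float, l_leg_rate: float) -> float:
        p = self.params
        f = mtu_force(
            a, p.mtu_length(l_leg), p.mtu_rate(l_leg_rate), p, lm_guess=self._lm
        )
        # refresh the cache from the solved equilibrium
        stretch = f / p.k_se
        self._lm = p.mtu_length(l_leg) - p.se_slack - stretch
        return p.alpha * f
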