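"""Closed-form triangular-force model of within-step vertical control.

Between two consecutive flight apexes the vertical velocity starts and ends at
zero, so the net vertical impulse always equals the gravity impulse: changing
the *total* vertical impulse cannot steer apex height.  What can steer it is
the *distribution* of impulse within the step.  Idealizing the step as a
single stance of duration ``Tstep`` with a triangular vertical force profile
(peak ``Fpeak`` at time ``tpeak``), impulse balance forces ``Fpeak = 2`` body
weights, and double integration of ``Fz - 1`` gives the apex-to-apex height
change

    dz = ((Tstep - tpeak)**2 - tpeak**2) / 6        (g = 1)

so a peak after mid-stance lowers the next apex and a peak before mid-stance
raises it.  These pure functions serve both as a standalone result and as a
sign oracle for the simulator's vertical feedback.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "triangular_peak_force",
    "triangular_force",
    "apex_height_change",
    "tpeak_for_height_change",
    "half_impulse_split",
]


def triangular_peak_force(Tstep: float, mass: float = 1.0, g: float = 1.0) -> float:
    """Peak of the impulse-balanced triangular force profile.

    The triangle's area ``Fpeak * Tstep / 2`` must equal the gravity impulse
    ``m * g * Tstep``, hence ``Fpeak = 2 m g`` for any step duration.
    """
    if Tstep <= 0:
        raise ValueError("Tstep must be positive")
    return 2.0 * mass * g


def triangular_force(t, Tstep: float, tpeak: float):
    """Triangular vertical force profile (body weights, g = 1)."""
    _check_tpeak(Tstep, tpeak)
    t = np.asarray(t, dtype=float)
    fpk = triangular_peak_force(Tstep)
    up = fpk * t / tpeak
    down = fpk * (Tstep - t) / (Tstep - tpeak)
    return np.clip(np.where(t <= tpeak, up, down), 0.0, None)


def apex_height_change(Tstep: float, tpeak: float, g: float = 1.0) -> float:
    """Change in vertical position over one step, z(Tstep) - z(0).

    Zero for a mid-stance-symmetric peak; strictly decreasing in ``tpeak``
    (delaying the peak lowers the next apex).
    """
    _check_tpeak(Tstep, tpeak)
    return g / 6.0 * ((Tstep - tpeak) ** 2 - tpeak**2)


def tpeak_for_height_change(Tstep: float, dz_target: float, g: float = 1.0) -> float:
    """Invert :func:`apex_height_change` for the peak time achieving ``dz_target``.

    The height change is linear in ``tpeak``:
    ``dz = (Tstep**2 - 2 Tstep tpeak) * g / 6``, so
    ``tpeak = (Tstep**2 - 6 dz / g) / (2 Tstep)``.
    """
    tpeak = (Tstep**2 - 6.0 * dz_target / g) / (2.0 * Tstep)
    if not (0.0 < tpeak < Tstep):
        raise ValueError(
            f"target height change {dz_target} is unreachable in one step "
            f"(requires tpeak={tpeak}, outside (0, {Tstep}))"
        )
    return tpeak


def half_impulse_split(Tstep: float, tpeak: float) -> tuple[float, float]:
    """Vertical impulse of the triangle over the two halves of the step.

    The halves always sum to the total gravity impulse ``Tstep`` (body-weight
    time units); a delayed peak shifts impulse from the first half to the
    second, which is how a high apex is brought back down.
    """
    _check_tpeak(Tstep, tpeak)
    fpk = triangular_peak_force(Tstep)
    tm = Tstep / 2.0
    if tpeak >= tm:
        # first half lies entirely on the rising flank
        first = 0.5 * tm * float(triangular_force(tm, Tstep, tpeak))
    else:
        # rising triangle plus trapezoid of the falling flank up to Tstep/2
        first = 0.5 * tpeak * fpk + 0.5 * (tm - tpeak) * (
            fpk + float(triangular_force(tm, Tstep, tpeak))
        )
    total = 0.5 * Tstep * fpk
    return first, total - first


def _check_tpeak(Tstep: float, tpeak: float) -> None:
    if Tstep <= 0:
        raise ValueError("Tstep must be positive")
    if not (0.0 < tpeak < Tstep):
        raise ValueError(f"tpeak must lie strictly inside (0, {Tstep}); got {tpeak}")
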