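"""Core state containers and unit conventions for the point-mass biped.

Everything internal is nondimensional: lengths in units of the maximum leg
length ``l_max``, time in units of ``sqrt(l_max / g)``, velocities in
``sqrt(g * l_max)``, forces in body weights (``m * g``), so that
``m = g = l_max = 1``.  Axes: ``x`` sideways, ``y`` fore-aft (direction of
travel), ``z`` vertical.  Dimensional (SI) quantities appear only at the file
IO boundary, converted through :class:`Scales`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "Scales",
    "BodyState",
    "ApexState",
    "FootAnchor",
    "StepRecord",
    "Terrain",
    "MIRROR",
]

#: Sign flips that mirror a (x, y, z) triple about the sagittal plane.
MIRROR = np.array([-1.0, 1.0, 1.0])


@dataclass(frozen=True)
class Scales:
    """Dimensional scales used to nondimensionalize recorded data.

    Parameters
    ----------
    mass_kg : body mass in kilograms.
    g : gravitational acceleration, m/s^2.
    leg_length_m : maximum leg length ``l_max`` in metres.
    """

    mass_kg: float = 66.8
    g: float = 9.81
    leg_length_m: float = 1.05

    @property
    def time_s(self) -> float:
        """Time unit sqrt(l_max / g), seconds."""
        return float(np.sqrt(self.leg_length_m / self.g))

    @property
    def speed_mps(self) -> float:
        """Velocity unit sqrt(g * l_max), m/s."""
        return float(np.sqrt(self.g * self.leg_length_m))

    @property
    def force_n(self) -> float:
        """Force unit: one body weight, newtons."""
        return self.mass_kg * self.g


@dataclass
class BodyState:
    """Instantaneous COM state, nondimensional."""

    x: float
    y: float
    z: float
    vx: float
    vy: float
    vz: float
    t: float = 0.0

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def vel(self) -> np.ndarray:
        return np.array([self.vx, self.vy, self.vz])

    def energy(self) -> float:
        """Total mechanical energy (m = g = 1): kinetic + potential."""
        return 0.5 * float(self.vel @ self.vel) + self.z

    def advance_ballistic(self, dt: float) -> "BodyState":
        """Closed-form parabolic free flight by ``dt``."""
        return BodyState(
            x=self.x + self.vx * dt,
            y=self.y + self.vy * dt,
            z=self.z + self.vz * dt - 0.5 * dt * dt,
            vx=self.vx,
            vy=self.vy,
            vz=self.vz - dt,
            t=self.t + dt,
        )

    def mirrored(self) -> "BodyState":
        return replace(self, x=-self.x, vx=-self.vx)


@dataclass
class ApexState:
    """COM state at flight apex (or end-of-stance substitute).

    ``side`` names the stance that *follows* this apex.  When the body leaves
    the ground already moving downward there is no true apex and the
    end-of-stance state stands in (``is_true_apex=False``).
    """

    xa: float
    ya: float
    za: float
    vxa: float
    vya: float
    side: str = "left"
    is_true_apex: bool = True
    t: float = 0.0
    vza: float = 0.0  # nonzero only for end-of-stance substitutes

    def as_body_state(self) -> BodyState:
        return BodyState(self.xa, self.ya, self.za, self.vxa, self.vya, self.vza, self.t)


@dataclass(frozen=True)
class FootAnchor:
    """Stance foot position; fixed for the duration of one stance."""

    xfoot: float
    yfoot: float
    zfoot: float = 0.0

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.xfoot, self.yfoot, self.zfoot])


@dataclass
class Terrain:
    """Ground height, evaluated only at touchdown targets.

    ``offsets`` may hold one height per step (cycled if shorter than the run);
    ``height_fn`` overrides it with a function of fore-aft position.
    """

    offsets: Optional[np.ndarray] = None
    height_fn: Optional[object] = None

    def height(self, step_index: int, y: float) -> float:
        if self.height_fn is not None:
            return float(self.height_fn(y))
        if self.offsets is not None and len(self.offsets) > 0:
            return float(self.offsets[step_index % len(self.offsets)])
        return 0.0


@dataclass
class StepRecord:
    """Everything recorded over one step (flight + stance + flight)."""

    index: int
    side: str
    apex_in: ApexState
    apex_out: Optional[ApexState]
    foot: Optional[FootAnchor]
    t_touchdown: float = np.nan
    t_takeoff: float = np.nan
    Tstance: float = np.nan
    Tflight: float = np.nan
    landing_length: float = np.nan
    # sampled over stance, integrator-grid density
    t_series: np.ndarray = field(default_factory=lambda: np.empty(0))
    grf_series: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    leg_length_series: np.ndarray = field(default_factory=lambda: np.empty(0))
    state_series: np.ndarray = field(default_factory=lambda: np.empty((0, 6)))
    Px: float = np.nan
    Py: float = np.nan
    Pz: float = np.nan
    net_leg_work: float = np.nan
    fell: bool = False
    fall_reason: str = ""
    # realized control (for ground-truth bundles)
    command: Optional[object] = None
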