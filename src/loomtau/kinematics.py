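"""Closed-form optics of a rigid sphere on a direct collision course.

A sphere of half-size (radius) ``R`` approaches the observer at constant
speed ``v`` and strikes it at time ``t_c``.  The object--observer distance
is ``d(t) = v (t_c - t)``, so the initial distance is ``d0 = v t_c``.  The
optical variables seen by the observer are the angular size

    theta(t) = 2 arctan(R / d(t)),

its rate of expansion

    theta_dot(t) = 2 R v / (d(t)^2 + R^2),

and the angular acceleration

    theta_ddot(t) = 4 R v^2 d(t) / (d(t)^2 + R^2)^2.

All angles are in radians; degree conversion happens only at I/O
boundaries.  Time zero is approach onset; traces never include the contact
instant itself, where the optical variables diverge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ApproachStimulus",
    "OpticalTrace",
    "distance",
    "angular_size",
    "angular_velocity",
    "angular_acceleration",
    "generate_trace",
]

#: Default simulation time step in seconds (1 ms resolves all filter
#: dynamics used by the looming functions).
DEFAULT_DT = 1e-3


@dataclass(frozen=True)
class ApproachStimulus:
    """Constant-velocity direct approach of a rigid sphere.

    Parameters
    ----------
    half_size_R : float
        Object radius (half of the diameter), metres, > 0.
    speed_v : float
        Approach speed, m/s, > 0.
    collision_time_tc : float
        Time of contact measured from approach onset, seconds, > 0.
    dt : float
        Sampling interval for generated traces, seconds.
    """

    half_size_R: float
    speed_v: float
    collision_time_tc: float
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if self.half_size_R <= 0:
            raise ValueError("half_size_R must be positive")
        if self.speed_v <= 0:
            raise ValueError("speed_v must be positive")
        if self.collision_time_tc <= 0:
            raise ValueError("collision_time_tc must be positive")
        if not 0 < self.dt < self.collision_time_tc:
            raise ValueError("dt must satisfy 0 < dt < collision_time_tc")

    @classmethod
    def from_diameter(
        cls, diameter: float, speed_v: float, collision_time_tc: float, dt: float = DEFAULT_DT
    ) -> "ApproachStimulus":
        """Build a stimulus from the object's diameter (O = 2R)."""
        return cls(diameter / 2.0, speed_v, collision_time_tc, dt)

    @property
    def initial_distance_d0(self) -> float:
        """Distance at approach onset, d0 = v * t_c."""
        return self.speed_v * self.collision_time_tc

    @property
    def x_ratio(self) -> float:
        """Half-size-to-speed ratio R/|v| in seconds, the parameter that
        governs the peak timing of looming detectors."""
        return self.half_size_R / self.speed_v

    def with_dt(self, dt: float) -> "ApproachStimulus":
        return replace(self, dt=dt)


@dataclass
class OpticalTrace:
    """Uniformly sampled optical variables of one approach."""

    times: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    theta_ddot: np.ndarray | None = None
    is_noisy: bool = False
    stimulus: ApproachStimulus | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.theta_dot = np.asarray(self.theta_dot, dtype=float)
        if self.theta_ddot is not None:
            self.theta_ddot = np.asarray(self.theta_ddot, dtype=float)
        n = len(self.times)
        if n == 0:
            raise ValueError("empty trace")
        if len(self.theta) != n or len(self.theta_dot) != n:
            raise ValueError("times, theta and theta_dot must have equal length")
        if self.theta_ddot is not None and len(self.theta_ddot) != n:
            raise ValueError("theta_ddot length mismatch")
        if n > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
                raise ValueError("times must be uniformly spaced")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            if self.stimulus is not None:
                return self.stimulus.dt
            raise ValueError("dt undefined for a single-sample trace")
        return float(self.times[1] - self.times[0])


def _check_time(stim: ApproachStimulus, t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t >= stim.collision_time_tc):
        raise ValueError(
            "post-collision time: t must lie in [0, t_c); "
            f"got values outside [0, {stim.collision_time_tc})"
        )
    return t


def distance(stim: ApproachStimulus, t):
    """Object--observer distance d(t) = v (t_c - t), metres."""
    t = _check_time(stim, t)
    return stim.speed_v * (stim.collision_time_tc - t)


def angular_size(stim: ApproachStimulus, t):
    """Angular size theta(t) = 2 arctan(R / d(t)), radians, in (0, pi)."""
    d = distance(stim, t)
    return 2.0 * np.arctan(stim.half_size_R / d)


def angular_velocity(stim: ApproachStimulus, t):
    """Rate of expansion theta_dot(t) = 2 R v / (d(t)^2 + R^2), rad/s."""
    d = distance(stim, t)
    R = stim.half_size_R
    return 2.0 * R * stim.speed_v / (d * d + R * R)


def angular_acceleration(stim: ApproachStimulus, t):
    """Angular acceleration theta_ddot = 4 R v^2 d / (d^2 + R^2)^2, rad/s^2.

    Along an approach this peaks where d = R / sqrt(3).
    """
    d = distance(stim, t)
    R = stim.half_size_R
    return 4.0 * R * stim.speed_v**2 * d / (d * d + R * R) ** 2


def generate_trace(
    stim: ApproachStimulus,
    t_start: float = 0.0,
    t_end: float | None = None,
    include_ddot: bool = False,
) -> OpticalTrace:
    """Sample the closed-form optical variables on a uniform grid.

    The grid is ``t_start, t_start + dt, ..., <= t_end`` with the stimulus'
    own ``dt``.  ``t_end`` defaults to the last grid point strictly before
    contact.
    """
    tc = stim.collision_time_tc
    if t_end is None:
        t_end = tc - stim.dt
    if not 0 <= t_start < t_end:
        raise ValueError("need 0 <= t_start < t_end")
    if t_end >= tc:
        raise ValueError("t_end must precede the collision time")
    n = int(np.floor((t_end - t_start) / stim.dt + 1e-9)) + 1
    if n < 1:
        raise ValueError("empty time grid")
    times = t_start + stim.dt * np.arange(n)
    trace = OpticalTrace(
        times=times,
        theta=angular_size(stim, times),
        theta_dot=angular_velocity(stim, times),
        theta_ddot=angular_acceleration(stim, times) if include_ddot else None,
        is_noisy=False,
        stimulus=stim,
    )
    return trace
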