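"""The simulated environment: a cruise-control car and its noisy sensors.

The plant is a linear-drag vehicle on a constant slope:

    m * dv/dt = throttle_gain * a - drag_coeff * v
                - m * g_eff * sin(slope) + m * d(t)

with ``a`` the controller's throttle action and ``d(t)`` an exogenous
step disturbance (wind, a change of slope). Units follow the labels used
throughout the experiments (km/h for velocity, km/h^2 for acceleration,
seconds for time) treated as self-consistent model units; no dimensional
conversion is attempted. The default parameters are package choices for a
plausible desk-scale car, not values from any reference table.

Deliberately, the plant is *not* the agent's generative model (the agent
assumes decay-to-target dynamics ``-alpha (x + v)``): regulation works
despite the mismatch, which is the point of approximate model-based
control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .generalized import GeneralizedVector

__all__ = [
    "CarModel",
    "CarState",
    "DisturbanceSchedule",
    "plant_step",
    "true_acceleration",
    "observe",
    "noise_std",
]


@dataclass
class CarModel:
    """Plant parameters (model units; defaults are package choices)."""

    mass: float = 1.0
    throttle_gain: float = 1.0
    drag_coeff: float = 0.3
    slope_deg: float = 4.0
    g_eff: float = 9.81

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise InvalidParameterError("mass must be positive")
        if self.drag_coeff < 0:
            raise InvalidParameterError("drag_coeff must be non-negative")

    @property
    def gravity_component(self) -> float:
        """Along-road deceleration from the slope, g_eff * sin(lambda)."""
        return self.g_eff * math.sin(math.radians(self.slope_deg))

    def equilibrium_action(self, velocity: float) -> float:
        """Throttle that holds the given velocity (zero acceleration)."""
        return (
            self.drag_coeff * velocity + self.mass * self.gravity_component
        ) / self.throttle_gain

    def terminal_velocity(self, action: float = 0.0, disturbance: float = 0.0) -> float:
        """Steady-state velocity for a constant action and disturbance."""
        if self.drag_coeff == 0:
            raise InvalidParameterError("terminal velocity undefined without drag")
        return (
            self.throttle_gain * action
            + self.mass * (disturbance - self.gravity_component)
        ) / self.drag_coeff

    def to_dict(self) -> dict:
        return {
            "mass": self.mass,
            "throttle_gain": self.throttle_gain,
            "drag_coeff": self.drag_coeff,
            "slope_deg": self.slope_deg,
            "g_eff": self.g_eff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CarModel":
        return cls(**d)


@dataclass
class CarState:
    """True plant state: velocity (km/h), acceleration (km/h^2), time (s)."""

    velocity: float = 0.0
    acceleration: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("velocity", "acceleration", "time"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidInputError(f"{name} must be finite")


@dataclass
class DisturbanceSchedule:
    """Step disturbances and set-point changes, as (time, value) lists.

    Step disturbances are additive and persist once switched on; the
    set-point schedule replaces the target from each listed time onward.
    Times must be non-decreasing within each list.
    """

    disturbances: list[tuple[float, float]] = field(default_factory=list)
    setpoints: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("disturbances", "setpoints"):
            times = [t for t, _ in getattr(self, name)]
            if any(b < a for a, b in zip(times, times[1:])):
                raise InvalidParameterError(f"{name} times must be non-decreasing")

    def disturbance_at(self, t: float) -> float:
        return sum(mag for onset, mag in self.disturbances if t >= onset)

    def setpoint_at(self, t: float, default: float) -> float:
        value = default
        for onset, target in self.setpoints:
            if t >= onset:
                value = target
        return value


def true_acceleration(
    model: CarModel, state: CarState, action: float, disturbance: float
) -> float:
    """Instantaneous acceleration of the car under the given forces."""
    if not np.isfinite(action):
        raise InvalidInputError("action must be finite")
    return (
        model.throttle_gain * action
        - model.drag_coeff * state.velocity
        - model.mass * model.gravity_component
    ) / model.mass + disturbance


def plant_step(
    model: CarModel,
    state: CarState,
    action: float,
    disturbance: float,
    dt: float,
) -> CarState:
    """Advance the car one explicit-Euler step of length dt."""
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    acc = true_acceleration(model, state, action, disturbance)
    return CarState(
        velocity=state.velocity + dt * acc,
        acceleration=acc,
        time=state.time + dt,
    )


def noise_std(true_log_prec: np.ndarray | None) -> np.ndarray | None:
    """Per-order noise standard deviations, exp(-gamma/2); None = noise-free."""
    if true_log_prec is None:
        return None
    return np.exp(-0.5 * np.asarray(true_log_prec, dtype=float))


def observe(
    state: CarState,
    true_log_prec: np.ndarray | None,
    rng: np.random.Generator | int,
) -> GeneralizedVector:
    """Noisy generalised observation of the car.

    The sensors report velocity and acceleration directly, each corrupted
    by independent zero-mean Gaussian noise of variance
    ``exp(-true_log_prec_k)``; ``true_log_prec=None`` gives noise-free
    readings. ``rng`` may be a Generator or a seed (a seed gives a
    bit-reproducible stream).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    psi = np.array([state.velocity, state.acceleration])
    std = noise_std(true_log_prec)
    if std is not None:
        psi = psi + np.broadcast_to(std, psi.shape) * rng.standard_normal(psi.shape)
    return GeneralizedVector(psi, ("km/h", "km/h^2"))
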