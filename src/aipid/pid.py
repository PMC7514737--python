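"""Textbook PID controllers, standard and velocity form.

These are the independent reference implementations used to check the
active-inference controller against classical control, not part of the
inference machinery itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["PIDGains", "pid_standard", "pid_velocity"]


@dataclass(frozen=True)
class PIDGains:
    """Proportional, integral and derivative gains (all non-negative)."""

    kp: float
    ki: float
    kd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kp", "ki", "kd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v!r}")


def pid_standard(error_series: np.ndarray, gains: PIDGains, dt: float) -> np.ndarray:
    """Standard-form PID on a uniformly sampled error signal.

    u_t = kp*e_t + ki * (trapezoidal integral of e up to t)
        + kd * (first difference of e)/dt

    The derivative at the first sample uses the forward difference.
    """
    e = np.asarray(error_series, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise InvalidInputError("error_series needs at least 2 samples")
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    integral = cumulative_trapezoid(e, dx=dt, initial=0.0)
    deriv = np.empty_like(e)
    deriv[1:] = np.diff(e) / dt
    deriv[0] = deriv[1]
    return gains.kp * e + gains.ki * integral + gains.kd * deriv


def pid_velocity(
    error: float, error_dot: float, error_ddot: float, gains: PIDGains
) -> float:
    """Velocity-form PID: the rate of the control signal.

    u_dot = ki*e + kp*e_dot + kd*e_ddot. Integrating this recovers the
    standard form up to the integration constant; the velocity form is
    the shape the active-inference action flow takes under strong priors,
    with (ki, kp, kd) playing the role of the sensory precisions at
    embedding orders 0, 1, 2.
    """
    return gains.ki * error + gains.kp * error_dot + gains.kd * error_ddot
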