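"""Recognition dynamics: the coupled gradient flows the agent integrates.

Perception follows the generalised gradient flow
``mu_x_dot = D mu_x - dF/dmu_x`` (the ``D mu_x`` drift keeps the
minimisation in a moving frame: at the minimum the motion of the mode
equals the mode of the motion). Action descends the same free energy
through the sensations it can change, ``a_dot = -dF/da``, with the
reflex-arc assumption that a unit of action moves every sensory order by
one unit (``dpsi_k/da = 1``). Gain adaptation updates the expected
sensory log-precisions with a damped second-order flow so that each gain
settles where its precision-weighted squared error balances the
log-precision penalty.

All flows are integrated with explicit Euler at a fixed ``dt``;
instability is detected and raised loudly rather than silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError, NumericalInstabilityError
from .generalized import GeneralizedVector
from .model import Beliefs, LinearGenerativeModel, free_energy_gradients, prediction_errors

__all__ = [
    "AgentConfig",
    "perceive_step",
    "act_step",
    "adapt_gains_step",
    "controller_step",
]


@dataclass
class AgentConfig:
    """Integration and adaptation settings for the recognition dynamics.

    ``kappa`` is the damping on the log-precision flow (5 in the
    adaptation experiments); the adaptation window ``[adapt_start,
    adapt_stop)`` follows the convention of letting the controller settle
    first and freezing the gains before probing with a disturbance.
    Learning rates default to 1: the flows are written without rate
    constants and the rates exist only as a stiffness control.
    """

    dt: float = 0.005
    learning_rate_states: float = 1.0
    learning_rate_action: float = 1.0
    kappa: float = 5.0
    adapt_gains: bool = False
    adapt_start: float = 30.0
    adapt_stop: float = 150.0
    mu_bound: float = 1e9

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.kappa < 0:
            raise InvalidParameterError("kappa must be non-negative")
        if self.learning_rate_states <= 0 or self.learning_rate_action <= 0:
            raise InvalidParameterError("learning rates must be positive")

    def to_dict(self) -> dict:
        return {
            "dt": self.dt,
            "learning_rate_states": self.learning_rate_states,
            "learning_rate_action": self.learning_rate_action,
            "kappa": self.kappa,
            "adapt_gains": self.adapt_gains,
            "adapt_start": self.adapt_start,
            "adapt_stop": self.adapt_stop,
            "mu_bound": self.mu_bound,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgentConfig":
        return cls(**d)


def perceive_step(
    model: LinearGenerativeModel,
    beliefs: Beliefs,
    psi: GeneralizedVector,
    config: AgentConfig,
) -> Beliefs:
    """One Euler step of the perception flow ``mu_dot = D mu - dF/dmu``."""
    mu = beliefs.mu_x.values
    grad_mu, _ = free_energy_gradients(model, beliefs, psi)
    mu_dot = -config.learning_rate_states * grad_mu
    mu_dot[:-1] += mu[1:]
    mu_new = mu + config.dt * mu_dot
    bad = np.abs(mu_new) > config.mu_bound
    if bad.any():
        order = int(np.argmax(bad))
        raise NumericalInstabilityError(
            f"expected hidden state at order {order} left the bound "
            f"{config.mu_bound:g} (|mu_{order}| = {abs(mu_new[order]):.3g}); "
            "the explicit-Euler step is too large for these precisions"
        )
    return replace(beliefs, mu_x=GeneralizedVector(mu_new, beliefs.mu_x.units))


def act_step(
    model: LinearGenerativeModel,
    beliefs: Beliefs,
    psi: GeneralizedVector,
    config: AgentConfig,
) -> Beliefs:
    """One Euler step of the action flow ``a_dot = -dF/da``.

    With ``dpsi_k/da = 1`` at every order this is
    ``a_dot = -sum_k pi_z_k * (psi_k - mu_k)``; when the expectations are
    pinned to the priors by strong process precisions it reduces to the
    velocity form of PID control with gains ``pi_z``.
    """
    eps_z, _ = prediction_errors(model, beliefs, psi)
    a_dot = -float(np.dot(beliefs.pi_z, eps_z))
    action = beliefs.action + config.dt * config.learning_rate_action * a_dot
    if not np.isfinite(action):
        raise NumericalInstabilityError("action diverged to a non-finite value")
    return replace(beliefs, action=action)


def adapt_gains_step(
    model: LinearGenerativeModel,
    beliefs: Beliefs,
    psi: GeneralizedVector,
    config: AgentConfig,
) -> Beliefs:
    """One Euler step of the damped log-precision (gain) flow.

    For each order k:

        d(mu_gamma_k)/dt  = mu_gamma_k'
        d(mu_gamma_k')/dt = -(exp(mu_gamma_k)*eps_z_k**2 - 1)/2
                            - kappa * mu_gamma_k'

    The stationary point balances the precision-weighted squared sensory
    error against the log-normalisation term; kappa > 0 damps the
    otherwise sustained oscillation around it.
    """
    _, grad_gamma = free_energy_gradients(model, beliefs, psi)
    gamma_dot = beliefs.mu_gamma_z_dot
    gamma_new = beliefs.mu_gamma_z + config.dt * gamma_dot
    gamma_dot_new = gamma_dot + config.dt * (-grad_gamma - config.kappa * gamma_dot)
    return replace(beliefs, mu_gamma_z=gamma_new, mu_gamma_z_dot=gamma_dot_new)


def controller_step(
    model: LinearGenerativeModel,
    beliefs: Beliefs,
    psi: GeneralizedVector,
    t: float,
    config: AgentConfig,
) -> Beliefs:
    """Perception, then action, then (inside the window) gain adaptation."""
    beliefs = perceive_step(model, beliefs, psi, config)
    beliefs = act_step(model, beliefs, psi, config)
    if config.adapt_gains and config.adapt_start <= t < config.adapt_stop:
        beliefs = adapt_gains_step(model, beliefs, psi, config)
    return beliefs
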