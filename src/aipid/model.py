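"""The agent's linear generative model and its Laplace-encoded free energy.

The agent assumes, at every embedding order k, a linear observation map
``psi_k = x_k + z_k`` and first-order linear dynamics
``x_k' = -alpha * (x_k + v_k) + w_k`` whose exogenous causes collapse to
the prior trajectory ``eta`` (prior-cause precisions are taken infinite,
so no cause prediction errors appear anywhere). Under Gaussian noise and
the Laplace approximation the variational free energy is a
precision-weighted sum of squared prediction errors minus log-precision
terms:

    F = 1/2 * sum_k [ pi_z_k * eps_z_k**2 + pi_w_k * eps_w_k**2
                      - ln(pi_z_k * pi_w_k) ]

with sensory errors ``eps_z_k = psi_k - mu_k`` and process (dynamics)
errors ``eps_w_k = mu_{k+1} + alpha * (mu_k - eta_k)`` (the expectation
one order above the highest retained order is truncated to zero).

Sensory precisions are parametrised as ``pi_z = exp(mu_gamma_z)`` through
the beliefs' expected log-precisions, which keeps them strictly positive
and is what makes online gain adaptation possible; process precisions are
fixed model parameters. With the expected log-precisions initialised to
the model's ``log_prec_z`` and never updated, the fixed-precision
formulation is recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .errors import DimensionMismatchError, InvalidInputError, InvalidParameterError
from .generalized import GeneralizedVector, log_precision_ladder

__all__ = [
    "LinearGenerativeModel",
    "Beliefs",
    "prediction_errors",
    "free_energy",
    "free_energy_gradients",
]


def _as_order_array(value: Any, n_orders: int, name: str) -> np.ndarray:
    """Broadcast a scalar to all orders or validate a per-order sequence."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_orders, float(arr))
    if arr.shape != (n_orders,):
        raise DimensionMismatchError(
            f"{name} must have one entry per order ({n_orders}), got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} must be finite")
    return arr


@dataclass
class LinearGenerativeModel:
    """Linear generative model in generalised coordinates.

    Parameters
    ----------
    alpha:
        Decay rate of the assumed hidden dynamics. Large alpha encodes the
        belief that the world relaxes (almost) instantly to the prior
        trajectory; 1e5 is used throughout the cruise-control experiments.
    eta:
        Prior (target) trajectory in generalised coordinates, e.g.
        ``(10, 0)`` for "hold 10 km/h with zero acceleration".
    log_prec_z, log_prec_w:
        Per-order sensory and process log-precisions. In the PID reading,
        ``exp(log_prec_z)`` at orders 0, 1, 2 are the integral,
        proportional and derivative gains.
    """

    alpha: float
    eta: GeneralizedVector
    log_prec_z: np.ndarray
    log_prec_w: np.ndarray
    n_orders: int = 0
    smoothness: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n_orders == 0:
            self.n_orders = self.eta.n_orders
        if self.alpha <= 0 or not np.isfinite(self.alpha):
            raise InvalidParameterError(f"alpha must be positive, got {self.alpha!r}")
        if self.eta.n_orders != self.n_orders:
            raise DimensionMismatchError(
                f"eta has {self.eta.n_orders} orders, model declares {self.n_orders}"
            )
        self.log_prec_z = _as_order_array(self.log_prec_z, self.n_orders, "log_prec_z")
        self.log_prec_w = _as_order_array(self.log_prec_w, self.n_orders, "log_prec_w")

    @classmethod
    def from_base(
        cls,
        alpha: float,
        eta0: float,
        base_log_prec_z: float,
        base_log_prec_w: float,
        smoothness: float = 0.5,
        n_orders: int = 2,
    ) -> "LinearGenerativeModel":
        """Build a model from base log-precisions and a smoothness ladder.

        The prior trajectory is the set-point ``eta0`` with all derivative
        orders zero (standard set-point regulation); per-order precisions
        decay geometrically with the smoothness factor.
        """
        eta = GeneralizedVector(np.r_[eta0, np.zeros(n_orders - 1)])
        return cls(
            alpha=alpha,
            eta=eta,
            log_prec_z=log_precision_ladder(base_log_prec_z, smoothness, n_orders),
            log_prec_w=log_precision_ladder(base_log_prec_w, smoothness, n_orders),
            n_orders=n_orders,
            smoothness=smoothness,
        )

    @property
    def pi_w(self) -> np.ndarray:
        return np.exp(self.log_prec_w)

    @property
    def pi_z(self) -> np.ndarray:
        """Fixed-mode sensory precisions (ignoring any adapted beliefs)."""
        return np.exp(self.log_prec_z)

    def set_target(self, eta0: float) -> None:
        """Move the set-point, keeping derivative priors unchanged."""
        values = self.eta.values.copy()
        values[0] = eta0
        self.eta = GeneralizedVector(values, self.eta.units)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "alpha": float(self.alpha),
            "eta": [float(v) for v in self.eta.values],
            "log_prec_z": [float(v) for v in self.log_prec_z],
            "log_prec_w": [float(v) for v in self.log_prec_w],
            "smoothness": self.smoothness,
            "n_orders": int(self.n_orders),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "LinearGenerativeModel":
        n = int(d.get("n_orders") or len(d["eta"]))
        smooth = d.get("smoothness")
        lpz, lpw = d["log_prec_z"], d["log_prec_w"]
        if np.ndim(lpz) == 0 and smooth is not None:
            lpz = log_precision_ladder(float(lpz), smooth, n)
        if np.ndim(lpw) == 0 and smooth is not None:
            lpw = log_precision_ladder(float(lpw), smooth, n)
        return cls(
            alpha=float(d["alpha"]),
            eta=GeneralizedVector(np.asarray(d["eta"], dtype=float)),
            log_prec_z=np.asarray(lpz, dtype=float),
            log_prec_w=np.asarray(lpw, dtype=float),
            n_orders=n,
            smoothness=smooth,
        )


@dataclass
class Beliefs:
    """The agent's variational (recognition) state.

    ``mu_x`` are the expected hidden states in generalised coordinates,
    ``action`` the scalar control, ``mu_gamma_z`` the expected sensory
    log-precisions (the log PID gains) and ``mu_gamma_z_dot`` their motion
    used by the damped second-order adaptation flow.
    """

    mu_x: GeneralizedVector
    action: float
    mu_gamma_z: np.ndarray
    mu_gamma_z_dot: np.ndarray

    def __post_init__(self) -> None:
        n = self.mu_x.n_orders
        self.mu_gamma_z = _as_order_array(self.mu_gamma_z, n, "mu_gamma_z")
        self.mu_gamma_z_dot = _as_order_array(
            self.mu_gamma_z_dot, n, "mu_gamma_z_dot"
        )
        if not np.isfinite(self.action):
            raise InvalidInputError("action must be finite")

    @classmethod
    def initial(
        cls,
        model: LinearGenerativeModel,
        mu_x: GeneralizedVector | None = None,
        action: float = 0.0,
    ) -> "Beliefs":
        """Beliefs at rest: expected log-precisions start at the model's."""
        if mu_x is None:
            mu_x = GeneralizedVector(np.zeros(model.n_orders))
        return cls(
            mu_x=mu_x,
            action=action,
            mu_gamma_z=model.log_prec_z.copy(),
            mu_gamma_z_dot=np.zeros(model.n_orders),
        )

    @property
    def pi_z(self) -> np.ndarray:
        """Current sensory precisions / PID gains, exp(mu_gamma_z)."""
        return np.exp(self.mu_gamma_z)


def _check_orders(model: LinearGenerativeModel, psi: GeneralizedVector) -> None:
    if psi.n_orders != model.n_orders:
        raise DimensionMismatchError(
            f"psi has {psi.n_orders} orders, model has {model.n_orders}"
        )


def prediction_errors(
    model: LinearGenerativeModel, beliefs: Beliefs, psi: GeneralizedVector
) -> tuple[np.ndarray, np.ndarray]:
    """Sensory and process prediction errors at every embedding order.

    Returns ``(eps_z, eps_w)`` with ``eps_z_k = psi_k - mu_k`` and
    ``eps_w_k = mu_{k+1} + alpha*(mu_k - eta_k)``, truncating the
    expectation above the highest order to zero.
    """
    _check_orders(model, psi)
    mu = beliefs.mu_x.values
    eps_z = psi.values - mu
    eps_w = model.alpha * (mu - model.eta.values)
    eps_w[:-1] += mu[1:]
    return eps_z, eps_w


def free_energy(
    model: LinearGenerativeModel,
    beliefs: Beliefs,
    psi: GeneralizedVector,
    use_expected_precisions: bool = True,
) -> float:
    """Laplace-encoded variational free energy of one generalised sample.

    Sensory precisions come from the beliefs' expected log-precisions
    (``use_expected_precisions=True``, the adaptive parametrisation) or
    from the model's fixed ``log_prec_z``; process precisions are always
    the model's. Deterministic in its inputs.
    """
    eps_z, eps_w = prediction_errors(model, beliefs, psi)
    log_pi_z = beliefs.mu_gamma_z if use_expected_precisions else model.log_prec_z
    pi_z = np.exp(log_pi_z)
    pi_w = model.pi_w
    return 0.5 * float(
        np.sum(pi_z * eps_z**2 + pi_w * eps_w**2 - log_pi_z - model.log_prec_w)
    )


def free_energy_gradients(
    model: LinearGenerativeModel, beliefs: Beliefs, psi: GeneralizedVector
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic dF/dmu_x and dF/dmu_gamma_z.

    For the expectations,

        dF/dmu_k = -pi_z_k*eps_z_k + pi_w_k*alpha*eps_w_k
                   + pi_w_{k-1}*eps_w_{k-1}          (k >= 1)

    the last term being the coupling of order k into the process error one
    order below; it is absent at k = 0. For the expected sensory
    log-precisions, dF/dmu_gamma_k = (exp(mu_gamma_k)*eps_z_k**2 - 1)/2.
    """
    eps_z, eps_w = prediction_errors(model, beliefs, psi)
    pi_z = beliefs.pi_z
    pi_w = model.pi_w
    grad_mu = -pi_z * eps_z + pi_w * model.alpha * eps_w
    grad_mu[1:] += pi_w[:-1] * eps_w[:-1]
    grad_gamma = 0.5 * (pi_z * eps_z**2 - 1.0)
    return grad_mu, grad_gamma
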