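import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aipid import Beliefs, GeneralizedVector, LinearGenerativeModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_model(
    n_orders=2,
    alpha=2.0,
    eta=None,
    log_prec_z=0.0,
    log_prec_w=0.0,
):
    """Small generative model with O(1) parameters for unit tests."""
    if eta is None:
        eta = np.r_[10.0, np.zeros(n_orders - 1)]
    return LinearGenerativeModel(
        alpha=alpha,
        eta=GeneralizedVector(np.asarray(eta, dtype=float)),
        log_prec_z=np.broadcast_to(np.asarray(log_prec_z, float), (n_orders,)).copy(),
        log_prec_w=np.broadcast_to(np.asarray(log_prec_w, float), (n_orders,)).copy(),
        n_orders=n_orders,
    )


def make_beliefs(model, mu=None, action=0.0):
    gv = None if mu is None else GeneralizedVector(np.asarray(mu, dtype=float))
    return Beliefs.initial(model, mu_x=gv, action=action)


@pytest.fixture
def small_model():
    return make_model()
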