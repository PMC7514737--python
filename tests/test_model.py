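import numpy as np
import pytest
import yaml
from scipy.optimize import minimize

from aipid import (
    GeneralizedVector,
    LinearGenerativeModel,
    free_energy,
    free_energy_gradients,
    prediction_errors,
)
from aipid.errors import DimensionMismatchError, InvalidParameterError
from conftest import make_beliefs, make_model


def reference_errors(alpha, mu, eta, psi):
    """Independent elementwise oracle for the prediction errors."""
    n = len(mu)
    eps_z = [psi[k] - mu[k] for k in range(n)]
    eps_w = [
        (mu[k + 1] if k + 1 < n else 0.0) + alpha * (mu[k] - eta[k]) for k in range(n)
    ]
    return np.array(eps_z), np.array(eps_w)


def reference_free_energy(log_pi_z, log_pi_w, eps_z, eps_w):
    """Independent scalar-loop oracle for the Laplace free energy."""
    total = 0.0
    for k in range(len(eps_z)):
        total += np.exp(log_pi_z[k]) * eps_z[k] ** 2
        total += np.exp(log_pi_w[k]) * eps_w[k] ** 2
        total -= log_pi_z[k] + log_pi_w[k]
    return 0.5 * total


class TestPredictionErrors:
    def test_equilibrium_all_zero(self):
        model = make_model(eta=[10.0, 0.0])
        beliefs = make_beliefs(model, mu=[10.0, 0.0])
        psi = GeneralizedVector([10.0, 0.0])
        eps_z, eps_w = prediction_errors(model, beliefs, psi)
        assert eps_z.tolist() == [0.0, 0.0]
        assert eps_w.tolist() == [0.0, 0.0]

    def test_direct_substitution(self):
        model = make_model(alpha=2.0, eta=[10.0, 0.0])
        beliefs = make_beliefs(model, mu=[9.0, 0.0])
        psi = GeneralizedVector([9.0, 0.0])
        eps_z, eps_w = prediction_errors(model, beliefs, psi)
        assert eps_z.tolist() == [0.0, 0.0]
        assert eps_w.tolist() == [-2.0, 0.0]

    @pytest.mark.parametrize("n_orders", [1, 2, 3])
    def test_matches_elementwise_oracle(self, rng, n_orders):
        for _ in range(20):
            alpha = rng.uniform(0.5, 3.0)
            mu, eta, psi = rng.normal(size=(3, n_orders)) * 5
            model = make_model(n_orders=n_orders, alpha=alpha, eta=eta)
            beliefs = make_beliefs(model, mu=mu)
            eps_z, eps_w = prediction_errors(model, beliefs, GeneralizedVector(psi))
            ref_z, ref_w = reference_errors(alpha, mu, eta, psi)
            np.testing.assert_allclose(eps_z, ref_z, rtol=1e-14)
            np.testing.assert_allclose(eps_w, ref_w, rtol=1e-14)

    def test_dimension_mismatch(self, small_model):
        beliefs = make_beliefs(small_model)
        with pytest.raises(DimensionMismatchError):
            prediction_errors(small_model, beliefs, GeneralizedVector([1.0, 2.0, 3.0]))


class TestFreeEnergy:
    def test_zero_errors_unit_precisions(self):
        model = make_model(n_orders=1, eta=[10.0])
        beliefs = make_beliefs(model, mu=[10.0])
        assert free_energy(model, beliefs, GeneralizedVector([10.0])) == 0.0

    def test_single_order_closed_form(self):
        # eps_z = 1 with precision 2, eps_w = 0 with precision 1
        model = make_model(n_orders=1, eta=[10.0], log_prec_z=np.log(2.0))
        beliefs = make_beliefs(model, mu=[10.0])
        F = free_energy(model, beliefs, GeneralizedVector([11.0]))
        assert F == pytest.approx(0.5 * (2.0 - np.log(2.0)), rel=1e-12)

    @pytest.mark.parametrize("n_orders", [1, 2, 3])
    def test_matches_scalar_loop_oracle(self, rng, n_orders):
        for _ in range(20):
            alpha = rng.uniform(0.5, 3.0)
            mu, eta, psi = rng.normal(size=(3, n_orders)) * 5
            lpz, lpw = rng.uniform(-2, 2, size=(2, n_orders))
            model = make_model(
                n_orders=n_orders, alpha=alpha, eta=eta, log_prec_z=lpz, log_prec_w=lpw
            )
            beliefs = make_beliefs(model, mu=mu)
            eps_z, eps_w = reference_errors(alpha, mu, eta, psi)
            expected = reference_free_energy(lpz, lpw, eps_z, eps_w)
            F = free_energy(model, beliefs, GeneralizedVector(psi))
            assert F == pytest.approx(expected, rel=1e-12)

    def test_depends_only_on_errors(self, rng):
        """Configurations producing identical error vectors score identically."""
        model = make_model(alpha=1.0, eta=[0.0, 0.0])
        shiftv = rng.normal()
        b1 = make_beliefs(model, mu=[1.0, 0.0])
        f1 = free_energy(model, b1, GeneralizedVector([2.0, 0.5]))
        # translate psi and mu together at order 0 with eta moved too:
        model2 = make_model(alpha=1.0, eta=[shiftv, 0.0])
        b2 = make_beliefs(model2, mu=[1.0 + shiftv, 0.0])
        f2 = free_energy(model2, b2, GeneralizedVector([2.0 + shiftv, 0.5]))
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_minimised_at_analytic_stationary_point(self, rng):
        """Numerical minimisation over mu agrees with the closed-form optimum.

        F is quadratic in mu, so the stationary point solves the linear
        system A mu = b obtained from the analytic gradient; a quasi-Newton
        search from random starts must land on the same point.
        """
        n = 2
        model = make_model(n_orders=n, alpha=1.5, eta=[3.0, 0.0],
                           log_prec_z=[0.5, 0.0], log_prec_w=[0.2, -0.3])
        psi = GeneralizedVector(rng.normal(size=n) * 3)

        def f(mu):
            return free_energy(model, make_beliefs(model, mu=mu), psi)

        def grad(mu):
            g, _ = free_energy_gradients(model, make_beliefs(model, mu=mu), psi)
            return g

        # linear system from the (exactly linear) gradient
        b = -grad(np.zeros(n))
        A = np.column_stack([grad(e) + b for e in np.eye(n)])
        mu_star = np.linalg.solve(A, b)
        for _ in range(3):
            res = minimize(
                f, rng.normal(size=n) * 10, jac=grad, method="BFGS",
                options={"gtol": 1e-10},
            )
            np.testing.assert_allclose(res.x, mu_star, rtol=1e-6, atol=1e-6)
        assert np.linalg.norm(grad(mu_star)) < 1e-8


class TestGradients:
    def test_analytic_matches_finite_differences(self, rng):
        h = 1e-5
        for _ in range(10):
            n = int(rng.integers(1, 4))
            model = make_model(
                n_orders=n,
                alpha=rng.uniform(0.5, 3.0),
                eta=rng.normal(size=n),
                log_prec_z=rng.uniform(-2, 2, n),
                log_prec_w=rng.uniform(-2, 2, n),
            )
            mu = rng.normal(size=n)
            gamma = rng.uniform(-2, 2, n)
            psi = GeneralizedVector(rng.normal(size=n))
            beliefs = make_beliefs(model, mu=mu)
            beliefs.mu_gamma_z = gamma
            g_mu, g_gamma = free_energy_gradients(model, beliefs, psi)
            for k in range(n):
                for target, analytic in (("mu", g_mu[k]), ("gamma", g_gamma[k])):
                    bp = make_beliefs(model, mu=mu)
                    bm = make_beliefs(model, mu=mu)
                    bp.mu_gamma_z = gamma.copy()
                    bm.mu_gamma_z = gamma.copy()
                    if target == "mu":
                        bp.mu_x.values[k] += h
                        bm.mu_x.values[k] -= h
                    else:
                        bp.mu_gamma_z[k] += h
                        bm.mu_gamma_z[k] -= h
                    fd = (
                        free_energy(model, bp, psi) - free_energy(model, bm, psi)
                    ) / (2 * h)
                    assert fd == pytest.approx(analytic, rel=1e-6, abs=1e-7)


class TestSerialisation:
    def test_round_trip_through_yaml(self):
        model = LinearGenerativeModel.from_base(
            alpha=1e5, eta0=10.0, base_log_prec_z=-3.0, base_log_prec_w=-22.0
        )
        text = yaml.safe_dump(model.to_dict())
        clone = LinearGenerativeModel.from_dict(yaml.safe_load(text))
        assert clone.to_dict() == model.to_dict()

    def test_scalar_base_with_smoothness_expands(self):
        d = {
            "alpha": 1e5,
            "eta": [10.0, 0.0],
            "log_prec_z": -3.0,
            "log_prec_w": -22.0,
            "smoothness": 0.5,
            "n_orders": 2,
        }
        model = LinearGenerativeModel.from_dict(d)
        np.testing.assert_allclose(model.pi_z, np.exp(-3.0) * np.array([1.0, 0.5]))

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(InvalidParameterError):
            make_model(alpha=0.0)
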