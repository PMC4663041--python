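import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import binom

from stscreen.graph import build_grid_lattice
from stscreen.model import (
    GammaPrior,
    HyperpriorSpec,
    ModelError,
    ModelState,
    deviance,
    deviance_from_eta,
    linear_predictor,
    log_likelihood,
    log_prior,
    loglik_from_eta,
)
from conftest import tiny_panel


def random_state(rng, I, T, p=0):
    v = rng.standard_normal(I)
    v -= v.mean()
    gamma = rng.standard_normal(T)
    gamma -= gamma.mean()
    return ModelState(
        alpha=float(rng.standard_normal()),
        u=rng.standard_normal(I),
        v=v,
        phi=rng.standard_normal(T),
        gamma=gamma,
        psi=rng.standard_normal((I, T)),
        beta=rng.standard_normal(p),
        tau_u=1.0, tau_v=2.0, tau_phi=3.0, tau_gamma=4.0, tau_psi=5.0,
    )


class TestLinearPredictor:
    def test_all_zero_gives_even_odds(self):
        state = ModelState.zeros(4, 3)
        assert np.all(linear_predictor(state) == 0.0)
        assert np.all(expit(linear_predictor(state)) == 0.5)

    def test_intercept_only_level(self):
        state = ModelState.zeros(5, 2)
        state.alpha = float(logit(0.48))
        assert np.allclose(expit(linear_predictor(state)), 0.48)

    def test_matches_naive_triple_loop(self, rng):
        I, T, p = 6, 3, 2
        state = random_state(rng, I, T, p)
        X = rng.standard_normal((I, T, p))
        eta = linear_predictor(state, X)
        for i in range(I):
            for t in range(T):
                expected = (
                    state.alpha + state.u[i] + state.v[i] + state.phi[t]
                    + state.gamma[t] + state.psi[i, t]
                    + sum(X[i, t, k] * state.beta[k] for k in range(p))
                )
                assert eta[i, t] == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_named(self, rng):
        state = random_state(rng, 4, 3, 1)
        with pytest.raises(ModelError, match="design matrix"):
            linear_predictor(state, np.zeros((4, 3, 2)))
        with pytest.raises(ModelError, match="beta"):
            linear_predictor(state, None)


class TestLogLikelihood:
    def test_single_bernoulli_cell(self):
        panel = tiny_panel([[1]], [[1]])
        assert loglik_from_eta(np.zeros((1, 1)), panel) == pytest.approx(np.log(0.5))

    def test_saturating_limit_from_below(self):
        panel = tiny_panel([[5]], [[5]])
        values = [loglik_from_eta(np.full((1, 1), eta), panel) for eta in (5, 20, 200)]
        assert values[0] < values[1] <= values[2] <= 0
        assert values[2] == pytest.approx(0.0, abs=1e-6)

    def test_stable_at_extreme_eta(self):
        panel = tiny_panel([[3]], [[10]])
        assert np.isfinite(loglik_from_eta(np.full((1, 1), -800.0), panel) )
        assert np.isfinite(loglik_from_eta(np.full((1, 1), 800.0), panel))

    def test_matches_textbook_binomial_logpmf(self, rng):
        I, T = 4, 3
        n = rng.integers(5, 80, size=(I, T)).astype(float)
        theta = rng.uniform(0.1, 0.9, size=(I, T))
        y = rng.binomial(n.astype(int), theta).astype(float)
        panel = tiny_panel(y, n)
        eta = logit(theta)
        oracle = binom.logpmf(y, n, theta).sum()
        assert loglik_from_eta(eta, panel) == pytest.approx(oracle, rel=1e-10)

    def test_concave_in_each_cell(self, rng):
        panel = tiny_panel([[7, 3], [2, 9]], [[10, 10], [12, 12]])
        eta0 = rng.standard_normal((2, 2))
        h = 1e-4
        for i in range(2):
            for t in range(2):
                d = np.zeros((2, 2)); d[i, t] = h
                second = (
                    loglik_from_eta(eta0 + d, panel)
                    - 2 * loglik_from_eta(eta0, panel)
                    + loglik_from_eta(eta0 - d, panel)
                ) / h**2
                assert second < 0

    def test_state_panel_mismatch(self, rng):
        state = random_state(rng, 3, 2)
        with pytest.raises(ModelError):
            log_likelihood(state, tiny_panel([[1, 1]], [[5, 5]]))


class TestLogPrior:
    def test_zero_structured_effect_leaves_log_precision_term(self, path3):
        hp = HyperpriorSpec()
        s0 = ModelState.zeros(3, 2, tau_v=2.0)
        s1 = ModelState.zeros(3, 2, tau_v=4.0)
        # with v = 0 the quadratic vanishes; doubling tau_v changes only
        # the ((I - c)/2) log tau_v term plus the Gamma hyperprior term
        diff = log_prior(s1, hp, path3) - log_prior(s0, hp, path3)
        expected = 0.5 * (3 - 1) * np.log(2.0) + hp.tau_v.logpdf(4.0) - hp.tau_v.logpdf(2.0)
        assert diff == pytest.approx(expected)

    def test_two_area_quadratic_is_4a_squared(self):
        g = build_grid_lattice(1, 2)
        hp = HyperpriorSpec()
        a = 0.7
        base = ModelState.zeros(2, 2, tau_v=1.0)
        tilted = ModelState.zeros(2, 2, tau_v=1.0)
        tilted.v = np.array([a, -a])
        # (v_1 - v_2)^2 = (2a)^2 = 4a^2, weighted by tau_v/2
        assert log_prior(base, hp, g) - log_prior(tilted, hp, g) == pytest.approx(0.5 * 4 * a**2)

    def test_doubling_tau_psi_at_zero_interaction(self, grid3):
        hp = HyperpriorSpec()
        s0 = ModelState.zeros(9, 3, tau_psi=1.0)
        s1 = ModelState.zeros(9, 3, tau_psi=2.0)
        diff = log_prior(s1, hp, grid3) - log_prior(s0, hp, grid3)
        expected = 0.5 * 9 * 3 * np.log(2.0) + hp.tau_psi.logpdf(2.0) - hp.tau_psi.logpdf(1.0)
        assert diff == pytest.approx(expected)

    def test_nonpositive_precision_has_zero_density(self, grid3):
        s = ModelState.zeros(9, 3)
        s.tau_u = -1.0
        assert log_prior(s, HyperpriorSpec(), grid3) == -np.inf

    def test_proper_prior_shrinks_growing_u(self, grid3):
        hp = HyperpriorSpec()
        values = []
        for scale in (0.0, 1.0, 2.0, 4.0):
            s = ModelState.zeros(9, 3)
            s.u = scale * np.ones(9)
            values.append(log_prior(s, hp, grid3))
        assert values == sorted(values, reverse=True)

    def test_rank_convention_on_disconnected_graph(self, disconnected):
        hp = HyperpriorSpec()
        s0 = ModelState.zeros(4, 2, tau_v=1.0)
        s1 = ModelState.zeros(4, 2, tau_v=np.e)
        diff = log_prior(s1, hp, disconnected) - log_prior(s0, hp, disconnected)
        expected = 0.5 * (4 - 2) + hp.tau_v.logpdf(np.e) - hp.tau_v.logpdf(1.0)
        assert diff == pytest.approx(expected)

    def test_joint_posterior_finite_for_any_valid_state(self, grid3, rng):
        hp = HyperpriorSpec()
        panel = tiny_panel(rng.integers(0, 50, (9, 3)).astype(float), np.full((9, 3), 60.0))
        for _ in range(20):
            s = random_state(rng, 9, 3)
            assert np.isfinite(log_prior(s, hp, grid3) + log_likelihood(s, panel))


class TestDeviance:
    def test_definitional_identity(self, rng):
        panel = tiny_panel([[4, 6]], [[10, 10]])
        s = random_state(rng, 1, 2)
        assert deviance(s, panel) == pytest.approx(-2.0 * log_likelihood(s, panel))

    def test_hand_computed_cell(self):
        # n=2, Y=1, theta=1/2: D = -2 [log C(2,1) + log(1/4)] = 1.3863
        panel = tiny_panel([[1]], [[2]])
        assert deviance_from_eta(np.zeros((1, 1)), panel) == pytest.approx(-2 * (np.log(2) + np.log(0.25)))
        assert deviance_from_eta(np.zeros((1, 1)), panel) == pytest.approx(1.3863, abs=1e-4)

    def test_saturated_fit_minimizes_deviance(self, rng):
        y = np.array([[3.0, 14.0], [9.0, 1.0]])
        n = np.array([[10.0, 20.0], [15.0, 8.0]])
        panel = tiny_panel(y, n)
        saturated = deviance_from_eta(logit(y / n), panel)
        random_devs = [
            deviance_from_eta(rng.standard_normal((2, 2)) * 2, panel) for _ in range(1000)
        ]
        assert saturated <= min(random_devs)


class TestModelState:
    def test_constraint_validation(self, grid3):
        s = ModelState.zeros(9, 3)
        s.validate(grid3)
        s.v = np.ones(9)
        with pytest.raises(ModelError, match="sum-to-zero"):
            s.validate(grid3)

    def test_per_component_constraint(self, disconnected):
        s = ModelState.zeros(4, 2)
        s.v = np.array([0.5, -0.5, 0.3, -0.3])
        s.validate(disconnected)
        s.v = np.array([0.5, 0.5, -0.5, -0.5])  # global sum zero, per-component not
        with pytest.raises(ModelError):
            s.validate(disconnected)

    def test_gamma_prior_mean(self):
        assert GammaPrior(1.0, 0.001).mean() == pytest.approx(1000.0)
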