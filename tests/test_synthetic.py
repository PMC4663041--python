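import numpy as np
import pytest
from scipy.special import expit, logit

from stscreen.graph import build_grid_lattice, icar_structure
from stscreen.simulate import (
    DEFAULT_PERIOD_RATES,
    LatentEffects,
    PopulationLaw,
    ScenarioConfig,
    default_scenario,
    sample_icar,
    simulate_covariates,
    simulate_effects,
    simulate_panel,
    simulate_study,
)
from conftest import small_scenario


def neighbor_correlation(graph, x):
    """Pearson correlation over (symmetrized) neighbour pairs."""
    pairs = np.array(graph.edges())
    a = np.concatenate([x[pairs[:, 0]], x[pairs[:, 1]]])
    b = np.concatenate([x[pairs[:, 1]], x[pairs[:, 0]]])
    return float(np.corrcoef(a, b)[0, 1])


class TestEffects:
    def test_fixed_seed_bit_identical(self, grid3):
        cfg = small_scenario(grid3, seed=3)
        e1, e2 = simulate_effects(cfg), simulate_effects(cfg)
        for name in ("u", "v", "phi", "gamma", "psi"):
            assert np.array_equal(getattr(e1, name), getattr(e2, name))

    def test_huge_precision_collapses_structured_effect(self, grid3):
        cfg = small_scenario(grid3, seed=1, tau_v=1e12)
        assert np.max(np.abs(simulate_effects(cfg).v)) < 1e-4

    def test_constraints_hold(self, grid3, disconnected):
        for g in (grid3, disconnected):
            cfg = small_scenario(g, seed=2)
            e = simulate_effects(cfg)
            assert abs(e.gamma.sum()) < 1e-10
            from stscreen.graph import connected_components
            for comp in connected_components(g):
                assert abs(e.v[comp].sum()) < 1e-10

    def test_icar_covariance_matches_pseudoinverse(self, grid3):
        # empirical covariance over 5000 exact draws vs tau^-1 * pinv(R)
        tau = 4.0
        rng = np.random.default_rng(99)
        draws = sample_icar(grid3, tau, rng, size=5000)
        emp = np.cov(draws.T)
        R = icar_structure(grid3)
        w, V = np.linalg.eigh(R)
        keep = w > 1e-9
        target = (V[:, keep] / (tau * w[keep])) @ V[:, keep].T
        scale = np.max(np.abs(target))
        assert np.max(np.abs(emp - target)) < 0.12 * scale


class TestPanel:
    def test_counts_within_bounds(self, grid3):
        cfg = small_scenario(grid3, seed=5)
        panel = simulate_panel(cfg, simulate_effects(cfg))
        assert np.all(panel.y >= 0)
        assert np.all(panel.y <= panel.n)

    def test_null_model_rate_is_half(self, grid3):
        cfg = small_scenario(grid3, seed=8, alpha=0.0,
                             tau_u=1e9, tau_v=1e9, tau_phi=1e9, tau_gamma=1e9, tau_psi=1e9)
        panel = simulate_panel(cfg, simulate_effects(cfg))
        pooled = panel.y.sum() / panel.n.sum()
        se = np.sqrt(0.25 / panel.n.sum())
        assert abs(pooled - 0.5) < 3 * se

    def test_binary_covariate_odds_ratio_exact(self):
        # theta odds for x=1 areas are exactly 0.94 times the x=0 odds
        graph = build_grid_lattice(1, 4)
        beta = np.log(0.94)
        eta = np.zeros((4, 2))
        X = np.zeros((4, 2, 1))
        X[2:, :, 0] = 1.0
        eta = eta + X[:, :, 0] * beta
        theta = expit(eta)
        odds = theta / (1 - theta)
        assert np.allclose(odds[2:] / odds[:2], 0.94)

    def test_aggregate_rate_tracks_alpha(self, rng):
        graph = build_grid_lattice(4, 5)
        cfg = ScenarioConfig(
            graph=graph, n_periods=2, alpha=float(logit(0.54)), beta=np.array([]),
            precisions={k: 1e9 for k in ("tau_u", "tau_v", "tau_phi", "tau_gamma", "tau_psi")},
            population_law=PopulationLaw(median=2000.0, dispersion=0.2), seed=4,
        )
        panel = simulate_panel(cfg, simulate_effects(cfg))
        pooled = panel.y.sum() / panel.n.sum()
        se = np.sqrt(0.54 * 0.46 / panel.n.sum())
        assert abs(pooled - 0.54) < 3 * se

    def test_pooled_mle_recovers_alpha(self, grid3):
        # with all effects switched off the pooled-count MLE of the level
        # converges to the configured alpha
        alpha = float(logit(0.43))
        cfg = small_scenario(grid3, seed=21, alpha=alpha,
                             tau_u=1e8, tau_v=1e8, tau_phi=1e8, tau_gamma=1e8, tau_psi=1e8)
        cfg = ScenarioConfig(graph=cfg.graph, n_periods=3, alpha=alpha, beta=np.array([]),
                             precisions=cfg.precisions,
                             population_law=PopulationLaw(median=5000.0, dispersion=0.1), seed=21)
        panel = simulate_panel(cfg, simulate_effects(cfg))
        pooled = panel.y.sum() / panel.n.sum()
        mle = logit(pooled)
        se_rate = np.sqrt(pooled * (1 - pooled) / panel.n.sum())
        se_logit = se_rate / (pooled * (1 - pooled))
        assert abs(mle - alpha) < 3 * se_logit

    def test_misaligned_design_rejected(self, grid3):
        cfg = small_scenario(grid3, seed=2, beta=[0.1])
        effects = simulate_effects(cfg)
        with pytest.raises(ValueError, match="misaligned"):
            simulate_panel(cfg, effects, X=np.zeros((9, 2, 1)))

    def test_seed_determinism_of_full_study(self, grid3):
        cfg = small_scenario(grid3, seed=13, beta=[-0.2])
        s1 = simulate_study(cfg)
        s2 = simulate_study(cfg)
        assert np.array_equal(s1.panel.y, s2.panel.y)
        assert np.array_equal(s1.design, s2.design)


class TestCovariates:
    def test_shape_is_areas_by_periods(self, grid3):
        cov = simulate_covariates(grid3, 3, 2, spatial_clustering=0.5, seed=1)
        assert cov.values.shape == (9, 3, 2)
        assert len(cov.to_frame()) == 9 * 3

    def test_clustering_dial_orders_neighbour_correlation(self):
        graph = build_grid_lattice(5, 8)
        wins = 0
        n_seeds = 100
        for seed in range(n_seeds):
            smooth = simulate_covariates(graph, 1, 1, spatial_clustering=1.0, seed=seed)
            rough = simulate_covariates(graph, 1, 1, spatial_clustering=0.0, seed=seed)
            r_smooth = neighbor_correlation(graph, smooth.values[:, 0, 0])
            r_rough = neighbor_correlation(graph, rough.values[:, 0, 0])
            wins += r_smooth > r_rough
        assert wins >= 95

    def test_zero_clustering_uncorrelated_on_average(self):
        graph = build_grid_lattice(5, 8)
        rs = [
            neighbor_correlation(graph, simulate_covariates(graph, 1, 1, 0.0, seed=s).values[:, 0, 0])
            for s in range(60)
        ]
        assert abs(np.mean(rs)) < 0.05

    def test_invalid_clustering_rejected(self, grid3):
        with pytest.raises(ValueError):
            simulate_covariates(grid3, 2, 1, spatial_clustering=1.5, seed=0)


class TestDefaultScenario:
    def test_design_dimensions(self):
        cfg = default_scenario()
        assert cfg.n_areas == 62
        assert cfg.n_periods == 3
        assert cfg.population_law.median == 4086.0
        assert np.allclose(np.exp(cfg.beta), 0.94)
        cfg_check = ScenarioConfig(**{**cfg.__dict__})  # passes its own invariants
        assert cfg_check.n_areas == 62

    def test_trend_reproduces_published_period_pattern(self):
        cfg = default_scenario()
        expected = expit(cfg.alpha + cfg.gamma_truth)
        assert np.allclose(expected, DEFAULT_PERIOD_RATES, atol=1e-12)
        assert abs(cfg.gamma_truth.sum()) < 1e-12

    def test_simulated_rates_near_targets_at_default_seed(self):
        study = simulate_study(default_scenario())
        rates = study.panel.overall_rates() * 100
        assert np.all(np.abs(rates - np.array([48.0, 50.0, 54.0])) < 1.5)

    def test_overall_level_near_one_half(self):
        cfg = default_scenario()
        assert abs(expit(cfg.alpha) - 0.5) < 0.01
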