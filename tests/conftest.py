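import numpy as np
import pytest

from stscreen.graph import AreaGraph, build_grid_lattice
from stscreen.mcmc import McmcConfig, PosteriorDraws, run_mcmc
from stscreen.model import PRECISION_NAMES, HyperpriorSpec
from stscreen.prep import PanelData
from stscreen.simulate import PopulationLaw, ScenarioConfig, simulate_effects, simulate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def path3():
    """A - B - C path graph."""
    return AreaGraph(("A", "B", "C"), ((1,), (0, 2), (1,)))


@pytest.fixture
def grid3():
    return build_grid_lattice(3, 3)


@pytest.fixture
def disconnected():
    """Two disjoint edges: {A,B} and {C,D}."""
    return AreaGraph(("A", "B", "C", "D"), ((1,), (0,), (3,), (2,)))


def small_scenario(graph, seed=0, alpha=0.0, beta=(), **precision_overrides):
    precisions = {"tau_u": 50.0, "tau_v": 25.0, "tau_phi": 100.0, "tau_gamma": 50.0, "tau_psi": 200.0}
    precisions.update(precision_overrides)
    return ScenarioConfig(
        graph=graph,
        n_periods=3,
        alpha=alpha,
        beta=np.asarray(beta, dtype=float),
        precisions=precisions,
        population_law=PopulationLaw(median=400.0, dispersion=0.3),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_fit():
    """A short but real fit on a 3x3 study, reused by summary/report tests."""
    graph = build_grid_lattice(3, 3)
    cfg = small_scenario(graph, seed=11)
    effects = simulate_effects(cfg)
    panel = simulate_panel(cfg, effects)
    mc = McmcConfig(n_iterations=2500, burn_in=800, thin=2, seed=5)
    draws = run_mcmc(panel, graph, HyperpriorSpec(), mc)
    return {"graph": graph, "cfg": cfg, "effects": effects, "panel": panel, "draws": draws}


def make_draws(alpha, u=None, v=None, phi=None, gamma=None, psi=None, beta=None,
               beta_names=(), n_areas=2, n_periods=2, deviance=None, X=None):
    """Fabricate a PosteriorDraws object with consistent shapes for
    summary-level tests that need controlled draw values."""
    alpha = np.asarray(alpha, dtype=float)
    n = alpha.shape[0]
    beta = np.zeros((n, len(beta_names))) if beta is None else np.asarray(beta, dtype=float)
    u = np.zeros((n, n_areas)) if u is None else np.asarray(u, dtype=float)
    v = np.zeros((n, n_areas)) if v is None else np.asarray(v, dtype=float)
    phi = np.zeros((n, n_periods)) if phi is None else np.asarray(phi, dtype=float)
    gamma = np.zeros((n, n_periods)) if gamma is None else np.asarray(gamma, dtype=float)
    psi = np.zeros((n, n_areas, n_periods)) if psi is None else np.asarray(psi, dtype=float)
    return PosteriorDraws(
        area_ids=tuple(f"a{i}" for i in range(n_areas)),
        beta_names=tuple(beta_names),
        alpha=alpha,
        beta=beta,
        u=u,
        v=v,
        phi=phi,
        gamma=gamma,
        psi=psi,
        tau={name: np.ones(n) for name in PRECISION_NAMES},
        deviance=np.zeros(n) if deviance is None else np.asarray(deviance, dtype=float),
        X=X,
        config=McmcConfig(n_iterations=max(n, 2), burn_in=0, thin=1, seed=0),
        acceptance={},
        max_residual_v=0.0,
        max_residual_gamma=0.0,
    )


def tiny_panel(y, n, area_ids=None):
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n = np.atleast_2d(np.asarray(n, dtype=float))
    if area_ids is None:
        area_ids = tuple(f"a{i}" for i in range(y.shape[0]))
    return PanelData(tuple(area_ids), y, n)
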