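"""Binomial-logit spatio-temporal model: state, likelihood, priors, deviance.

The observation model is ``Y_it ~ Binomial(n_it, theta_it)`` with

    logit theta_it = alpha + u_i + v_i + phi_t + gamma_t + psi_it + x_it' beta

where ``u`` is an iid (unstructured) spatial effect, ``v`` a structured
spatial effect with an intrinsic-CAR prior on the area graph, ``phi`` an iid
temporal effect, ``gamma`` a first-order random-walk temporal trend, and
``psi`` an iid space-time interaction.  ``v`` and ``gamma`` carry hard
sum-to-zero constraints (per graph component for ``v``) so that the
intercept identifies the overall participation level.  Every precision gets
a Gamma(shape, rate) hyperprior, stated on the log-precision scale by the
approximate-inference convention ("logGamma"), which is the same thing as a
Gamma prior on the precision itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .graph import AreaGraph, connected_components
from .prep import PanelData

__all__ = [
    "GammaPrior",
    "HyperpriorSpec",
    "ModelState",
    "ModelError",
    "linear_predictor",
    "log_likelihood",
    "loglik_from_eta",
    "log_prior",
    "deviance",
    "deviance_from_eta",
    "PRECISION_NAMES",
]

PRECISION_NAMES = ("tau_u", "tau_v", "tau_phi", "tau_gamma", "tau_psi")


class ModelError(ValueError):
    """Inconsistent model state or data."""


@dataclass(frozen=True)
class GammaPrior:
    shape: float
    rate: float

    def mean(self) -> float:
        return self.shape / self.rate

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        return (
            self.shape * np.log(self.rate)
            - gammaln(self.shape)
            + (self.shape - 1.0) * np.log(x)
            - self.rate * x
        )


@dataclass(frozen=True)
class HyperpriorSpec:
    """Gamma hyperpriors on the five precisions, plus fixed-effect priors.

    Defaults are the minimally-informative choices customary for this model
    family: Gamma(1, 0.001) on both spatial precisions, Gamma(1, 0.01) on
    the unstructured temporal precision, and Gamma(1, 0.00005) on the
    random-walk and interaction precisions.  The intercept prior is flat by
    default (``alpha_precision = 0``); covariate coefficients get a vague
    zero-mean normal with precision 0.001.
    """

    tau_u: GammaPrior = field(default_factory=lambda: GammaPrior(1.0, 0.001))
    tau_v: GammaPrior = field(default_factory=lambda: GammaPrior(1.0, 0.001))
    tau_phi: GammaPrior = field(default_factory=lambda: GammaPrior(1.0, 0.01))
    tau_gamma: GammaPrior = field(default_factory=lambda: GammaPrior(1.0, 0.00005))
    tau_psi: GammaPrior = field(default_factory=lambda: GammaPrior(1.0, 0.00005))
    alpha_mean: float = 0.0
    alpha_precision: float = 0.0
    beta_precision: float = 0.001

    def gamma_prior(self, name: str) -> GammaPrior:
        if name not in PRECISION_NAMES:
            raise ModelError(f"unknown precision {name!r}")
        return getattr(self, name)


@dataclass
class ModelState:
    """One configuration of all model unknowns."""

    alpha: float
    u: np.ndarray
    v: np.ndarray
    phi: np.ndarray
    gamma: np.ndarray
    psi: np.ndarray
    beta: np.ndarray
    tau_u: float
    tau_v: float
    tau_phi: float
    tau_gamma: float
    tau_psi: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))

    @property
    def n_areas(self) -> int:
        return self.u.shape[0]

    @property
    def n_periods(self) -> int:
        return self.phi.shape[0]

    def precisions(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PRECISION_NAMES}

    def validate(self, graph: AreaGraph | None = None, rtol: float = 1e-8) -> None:
        I, T = self.n_areas, self.n_periods
        if self.v.shape != (I,) or self.psi.shape != (I, T) or self.gamma.shape != (T,):
            raise ModelError("effect dimensions are inconsistent")
        for name, value in self.precisions().items():
            if not value > 0:
                raise ModelError(f"{name} must be strictly positive, got {value}")
        scale = max(float(np.linalg.norm(self.gamma)), 1.0)
        if abs(float(self.gamma.sum())) > rtol * scale:
            raise ModelError("gamma violates its sum-to-zero constraint")
        comps = [list(range(I))] if graph is None else connected_components(graph)
        vscale = max(float(np.linalg.norm(self.v)), 1.0)
        for comp in comps:
            if abs(float(self.v[comp].sum())) > rtol * vscale:
                raise ModelError("v violates its per-component sum-to-zero constraint")

    @classmethod
    def zeros(cls, n_areas: int, n_periods: int, n_covariates: int = 0, **taus: float) -> "ModelState":
        defaults = dict(tau_u=1.0, tau_v=1.0, tau_phi=1.0, tau_gamma=1.0, tau_psi=1.0)
        defaults.update(taus)
        return cls(
            alpha=0.0,
            u=np.zeros(n_areas),
            v=np.zeros(n_areas),
            phi=np.zeros(n_periods),
            gamma=np.zeros(n_periods),
            psi=np.zeros((n_areas, n_periods)),
            beta=np.zeros(n_covariates),
            **defaults,
        )


def _check_X(state: ModelState, X: np.ndarray | None) -> np.ndarray | None:
    if X is None:
        if state.beta.size:
            raise ModelError("state carries beta but no covariate design was given")
        return None
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ModelError("design matrix must have shape (areas, periods, covariates)")
    if X.shape != (state.n_areas, state.n_periods, state.beta.size):
        raise ModelError(
            f"design matrix shape {X.shape} does not match "
            f"(I, T, p) = ({state.n_areas}, {state.n_periods}, {state.beta.size})"
        )
    return X


def linear_predictor(state: ModelState, X: np.ndarray | None = None) -> np.ndarray:
    """The I x T matrix of logit participation probabilities."""
    X = _check_X(state, X)
    eta = (
        state.alpha
        + state.u[:, None]
        + state.v[:, None]
        + state.phi[None, :]
        + state.gamma[None, :]
        + state.psi
    )
    if X is not None and state.beta.size:
        eta = eta + X @ state.beta
    return eta


def _binom_const(panel: PanelData) -> float:
    y, n = panel.y, panel.n
    return float(np.sum(gammaln(n + 1.0) - gammaln(y + 1.0) - gammaln(n - y + 1.0)))


def loglik_from_eta(eta: np.ndarray, panel: PanelData, include_const: bool = True) -> float:
    """Binomial log likelihood at a given linear predictor, stable at extreme eta.

    Uses ``y*eta - n*log(1 + exp(eta))`` with ``log1p(exp(.))`` evaluated as
    ``logaddexp(0, .)``; the binomial coefficient is a data constant.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != panel.y.shape:
        raise ModelError(f"eta shape {eta.shape} does not match panel {panel.y.shape}")
    core = float(np.sum(panel.y * eta - panel.n * np.logaddexp(0.0, eta)))
    return core + (_binom_const(panel) if include_const else 0.0)


def log_likelihood(state: ModelState, panel: PanelData, X: np.ndarray | None = None) -> float:
    if (state.n_areas, state.n_periods) != (panel.n_areas, panel.n_periods):
        raise ModelError("state dimensions do not match the panel")
    return loglik_from_eta(linear_predictor(state, X), panel)


def icar_quadratic(v: np.ndarray, graph: AreaGraph) -> float:
    """``sum over neighbour pairs (v_i - v_j)^2`` (each unordered pair once)."""
    edges = graph.edges()
    if not edges:
        return 0.0
    i, j = np.array(edges).T
    return float(np.sum((v[i] - v[j]) ** 2))


def rw1_quadratic(gamma: np.ndarray) -> float:
    return float(np.sum(np.diff(gamma) ** 2))


def _iid_logpdf(x: np.ndarray, tau: float) -> float:
    d = x.size
    return 0.5 * d * (np.log(tau) - np.log(2.0 * np.pi)) - 0.5 * tau * float(np.sum(x**2))


def log_prior(state: ModelState, hp: HyperpriorSpec, graph: AreaGraph) -> float:
    """Joint log prior of all effects and precisions.

    The improper ICAR and RW1 densities use the rank convention: the
    log-precision term enters with rank/2 degrees of freedom (``I - c`` for
    the ICAR with ``c`` graph components, ``T - 1`` for the random walk) and
    no normalizing constant beyond that.  States with non-positive
    precisions have prior density zero.
    """
    for value in state.precisions().values():
        if not value > 0:
            return -np.inf
    I, T = state.n_areas, state.n_periods
    c = len(connected_components(graph))
    lp = 0.0
    lp += _iid_logpdf(state.u, state.tau_u)
    lp += 0.5 * (I - c) * np.log(state.tau_v) - 0.5 * state.tau_v * icar_quadratic(state.v, graph)
    lp += _iid_logpdf(state.phi, state.tau_phi)
    lp += 0.5 * (T - 1) * np.log(state.tau_gamma) - 0.5 * state.tau_gamma * rw1_quadratic(state.gamma)
    lp += _iid_logpdf(state.psi.ravel(), state.tau_psi)
    for name in PRECISION_NAMES:
        lp += hp.gamma_prior(name).logpdf(getattr(state, name))
    if hp.alpha_precision > 0:
        lp += 0.5 * (np.log(hp.alpha_precision) - np.log(2.0 * np.pi))
        lp -= 0.5 * hp.alpha_precision * (state.alpha - hp.alpha_mean) ** 2
    if state.beta.size and hp.beta_precision > 0:
        lp += _iid_logpdf(state.beta, hp.beta_precision)
    return float(lp)


def deviance_from_eta(eta: np.ndarray, panel: PanelData) -> float:
    return -2.0 * loglik_from_eta(eta, panel)


def deviance(state: ModelState, panel: PanelData, X: np.ndarray | None = None) -> float:
    """``D = -2 log L``, binomial coefficient included."""
    return -2.0 * log_likelihood(state, panel, X)
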