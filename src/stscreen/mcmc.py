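"""Posterior sampling for the spatio-temporal binomial-logit model.

The sampler is Metropolis-within-Gibbs.  Precisions are exact conjugate
Gibbs draws from their Gamma full conditionals; the intercept, covariate
coefficients and every latent effect move by random-walk proposals whose
scales adapt toward a 44% acceptance rate during burn-in.  Updates of the
iid blocks (``u``, ``phi``, ``psi``) are single-site and, because both their
priors and the binomial likelihood factorize, all sites of a block are
proposed and accepted in parallel.  The ICAR block ``v`` is updated by
graph colouring: sites within one colour class share no edge, so their
single-site acceptances are again independent and vectorize.

Sum-to-zero constraints are hard.  Single-site moves of ``v`` (and of the
random-walk trend ``gamma``) are composed with an exact re-centring that
shifts the removed mean into the intercept; the likelihood and the
(translation-invariant) improper priors are unchanged by that shift, so
under the default flat intercept prior the composite move has the
constrained posterior as its invariant law, and the constraint residual is
zero after every sweep.  With a proper normal intercept prior the shift's
prior ratio enters the acceptance probability and the ``v`` sites are
updated sequentially; the same sequential path serves disconnected graphs,
where the shift leaks across components and the full likelihood difference
is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .graph import AreaGraph, connected_components
from .model import (
    PRECISION_NAMES,
    HyperpriorSpec,
    ModelError,
    ModelState,
    deviance_from_eta,
)
from .prep import PanelData
from .simulate import sample_icar, sample_rw1

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "PosteriorSummary",
    "run_mcmc",
    "summarize",
    "summary_from_sample",
    "odds_ratio_summary",
    "effect_surfaces",
]

ALL_TERMS = ("u", "v", "phi", "gamma", "psi")
_ADAPT_TARGET = 0.44
_ADAPT_BATCH = 50
_DEFAULT_SCALES = {
    "alpha": 0.05,
    "beta": 0.05,
    "u": 0.1,
    "v": 0.1,
    "phi": 0.05,
    "gamma": 0.02,
    "psi": 0.1,
    "shift_u": 0.05,
    "shift_phi": 0.05,
    "shift_psi": 0.05,
    "beta_u": 0.05,
    "scale_u": 0.3,
    "scale_v": 0.3,
    "scale_phi": 0.3,
    "scale_gamma": 0.3,
    "scale_psi": 0.3,
}


@dataclass(frozen=True)
class McmcConfig:
    """Chain length, tuning and reproducibility settings."""

    n_iterations: int = 5000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    step_scales: Mapping[str, float] = field(default_factory=dict)
    adapt: bool = True
    terms: tuple[str, ...] = ALL_TERMS
    sample_precisions: bool = True
    initial_precisions: Mapping[str, float] | None = None
    prior_only: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations <= 0 or self.thin <= 0:
            raise ValueError("n_iterations and thin must be positive")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        unknown = set(self.terms) - set(ALL_TERMS)
        if unknown:
            raise ValueError(f"unknown model terms {sorted(unknown)}")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    sd: float
    q2_5: float
    q50: float
    q97_5: float
    significant: bool | None = None  # for odds ratios: CI excludes 1


@dataclass
class PosteriorDraws:
    """Retained MCMC output: one model state per row plus its deviance."""

    area_ids: tuple[str, ...]
    beta_names: tuple[str, ...]
    alpha: np.ndarray
    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray
    phi: np.ndarray
    gamma: np.ndarray
    psi: np.ndarray
    tau: dict[str, np.ndarray]
    deviance: np.ndarray
    X: np.ndarray | None
    config: McmcConfig
    acceptance: dict[str, float]
    max_residual_v: float
    max_residual_gamma: float

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_areas(self) -> int:
        return self.u.shape[1]

    @property
    def n_periods(self) -> int:
        return self.phi.shape[1]

    def state(self, k: int) -> ModelState:
        return ModelState(
            alpha=float(self.alpha[k]),
            u=self.u[k],
            v=self.v[k],
            phi=self.phi[k],
            gamma=self.gamma[k],
            psi=self.psi[k],
            beta=self.beta[k],
            **{name: float(self.tau[name][k]) for name in PRECISION_NAMES},
        )

    def eta_draws(self) -> np.ndarray:
        """Linear predictor per retained draw, shape (n_draws, I, T)."""
        eta = (
            self.alpha[:, None, None]
            + self.u[:, :, None]
            + self.v[:, :, None]
            + self.phi[:, None, :]
            + self.gamma[:, None, :]
            + self.psi
        )
        if self.X is not None and self.beta.shape[1]:
            eta = eta + np.einsum("itp,kp->kit", self.X, self.beta)
        return eta

    def theta_draws(self) -> np.ndarray:
        return expit(self.eta_draws())

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"alpha": self.alpha}
        for j, name in enumerate(self.beta_names):
            cols[f"beta.{name}"] = self.beta[:, j]
        for i, a in enumerate(self.area_ids):
            cols[f"u.{a}"] = self.u[:, i]
        for i, a in enumerate(self.area_ids):
            cols[f"v.{a}"] = self.v[:, i]
        for t in range(self.n_periods):
            cols[f"phi.{t + 1}"] = self.phi[:, t]
        for t in range(self.n_periods):
            cols[f"gamma.{t + 1}"] = self.gamma[:, t]
        for i, a in enumerate(self.area_ids):
            for t in range(self.n_periods):
                cols[f"psi.{a}.{t + 1}"] = self.psi[:, i, t]
        for name in PRECISION_NAMES:
            cols[name] = self.tau[name]
        cols["deviance"] = self.deviance
        return pd.DataFrame(cols)

    def save(self, directory: str | Path) -> None:
        """Columnar CSV of the draws plus a JSON sidecar with run metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "draws.csv", index=False)
        meta = {
            "area_ids": list(self.area_ids),
            "beta_names": list(self.beta_names),
            "n_periods": self.n_periods,
            "config": _config_to_dict(self.config),
            "acceptance": self.acceptance,
            "max_residual_v": self.max_residual_v,
            "max_residual_gamma": self.max_residual_gamma,
            "X": None if self.X is None else self.X.tolist(),
        }
        (directory / "draws.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorDraws":
        directory = Path(directory)
        meta = json.loads((directory / "draws.json").read_text())
        df = pd.read_csv(directory / "draws.csv")
        area_ids = tuple(meta["area_ids"])
        beta_names = tuple(meta["beta_names"])
        T = meta["n_periods"]
        n = len(df)
        I = len(area_ids)
        psi = np.empty((n, I, T))
        for i, a in enumerate(area_ids):
            for t in range(T):
                psi[:, i, t] = df[f"psi.{a}.{t + 1}"]
        return cls(
            area_ids=area_ids,
            beta_names=beta_names,
            alpha=df["alpha"].to_numpy(),
            beta=np.column_stack([df[f"beta.{b}"] for b in beta_names]) if beta_names else np.empty((n, 0)),
            u=np.column_stack([df[f"u.{a}"] for a in area_ids]),
            v=np.column_stack([df[f"v.{a}"] for a in area_ids]),
            phi=np.column_stack([df[f"phi.{t + 1}"] for t in range(T)]),
            gamma=np.column_stack([df[f"gamma.{t + 1}"] for t in range(T)]),
            psi=psi,
            tau={name: df[name].to_numpy() for name in PRECISION_NAMES},
            deviance=df["deviance"].to_numpy(),
            X=None if meta["X"] is None else np.asarray(meta["X"]),
            config=McmcConfig(**{**meta["config"], "step_scales": dict(meta["config"]["step_scales"]), "terms": tuple(meta["config"]["terms"])}),
            acceptance=dict(meta["acceptance"]),
            max_residual_v=meta["max_residual_v"],
            max_residual_gamma=meta["max_residual_gamma"],
        )


def _config_to_dict(cfg: McmcConfig) -> dict:
    d = asdict(cfg)
    d["step_scales"] = dict(cfg.step_scales)
    d["terms"] = list(cfg.terms)
    if d["initial_precisions"] is not None:
        d["initial_precisions"] = dict(d["initial_precisions"])
    return d


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class _Adapter:
    """Robbins–Monro step-scale adaptation toward a target acceptance rate."""

    def __init__(self, scales: dict[str, float], enabled: bool):
        self.log_scale = {k: np.log(s) for k, s in scales.items()}
        self.enabled = enabled
        self.batch_acc: dict[str, list[float]] = {k: [] for k in scales}
        self.n_batches = 0

    def record(self, block: str, rate: float) -> None:
        self.batch_acc[block].append(rate)

    def maybe_adapt(self, iteration: int, in_burn_in: bool) -> None:
        if not self.enabled or not in_burn_in or (iteration + 1) % _ADAPT_BATCH:
            return
        self.n_batches += 1
        delta = min(0.1, 1.0 / np.sqrt(self.n_batches))
        for block, rates in self.batch_acc.items():
            if rates:
                mean_rate = float(np.mean(rates))
                self.log_scale[block] += delta if mean_rate > _ADAPT_TARGET else -delta
            self.batch_acc[block] = []

    def scale(self, block: str) -> float:
        return float(np.exp(self.log_scale[block]))


def run_mcmc(
    panel: PanelData,
    graph: AreaGraph,
    hp: HyperpriorSpec,
    cfg: McmcConfig,
    X: np.ndarray | None = None,
    beta_names: Iterable[str] | None = None,
) -> PosteriorDraws:
    """Sample the posterior of the full spatio-temporal model.

    ``X`` is an ``(I, T, p)`` covariate design; omit it for the
    covariate-free model.  A fixed seed yields a bit-identical chain.
    """
    I, T = panel.n_areas, panel.n_periods
    if graph.n_areas != I:
        raise ModelError("graph and panel disagree on the number of areas")
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[:2] != (I, T):
            raise ModelError(f"design matrix shape {X.shape} does not match panel ({I}, {T})")
    p = 0 if X is None else X.shape[2]
    if beta_names is None:
        beta_names = tuple(f"x{j + 1}" for j in range(p))
    else:
        beta_names = tuple(beta_names)
        if len(beta_names) != p:
            raise ModelError("beta_names length does not match the design matrix")
    terms = tuple(t for t in ALL_TERMS if t in cfg.terms)
    if "gamma" in terms and T < 2:
        raise ModelError("the random-walk trend needs at least two periods")

    rng = np.random.default_rng(cfg.seed)
    y, n = panel.y, panel.n
    sum_y = float(y.sum())
    row_y = y.sum(axis=1)
    col_y = y.sum(axis=0)

    comps = connected_components(graph)
    comp_of = np.empty(I, dtype=int)
    for ci, comp in enumerate(comps):
        comp_of[comp] = ci
    comp_size = np.array([len(c) for c in comps], dtype=float)
    connected = len(comps) == 1
    deg = graph.degrees()
    W = graph.adjacency_matrix()
    edges = np.array(graph.edges()).reshape(-1, 2)
    coloring = nx.coloring.greedy_color(graph.to_networkx(), strategy="smallest_last")
    n_colors = 1 + max(coloring.values(), default=0)
    color_classes = [np.array([i for i in range(I) if coloring.get(i, 0) == c], dtype=int) for c in range(n_colors)]
    color_classes = [cc for cc in color_classes if cc.size]
    fast_v = connected and hp.alpha_precision == 0.0

    # --- initial state: pooled-rate intercept, zero effects, prior-mean precisions
    pooled = sum_y / float(n.sum())
    if not 0.0 < pooled < 1.0:
        raise ModelError(f"pooled participation rate {pooled:g} leaves the intercept undefined")
    alpha = float(logit(pooled))
    beta = np.zeros(p)
    u = np.zeros(I)
    v = np.zeros(I)
    phi = np.zeros(T)
    gam = np.zeros(T)
    psi = np.zeros((I, T))
    tau = {name: hp.gamma_prior(name).mean() for name in PRECISION_NAMES}
    if cfg.initial_precisions:
        tau.update({k: float(val) for k, val in cfg.initial_precisions.items()})
    for name, value in tau.items():
        if not value > 0:
            raise ModelError(f"initial {name} must be positive")

    eta = np.full((I, T), alpha)
    if p:
        eta = eta + X @ beta
        xbar = X.mean(axis=1)  # (I, p) area-average covariate pattern
    sp = _softplus(eta)

    # Gibbs shapes for the precisions
    gibbs_shape = {
        "tau_u": I / 2.0,
        "tau_v": (I - len(comps)) / 2.0,
        "tau_phi": T / 2.0,
        "tau_gamma": (T - 1) / 2.0,
        "tau_psi": I * T / 2.0,
    }
    term_of_tau = {"tau_u": "u", "tau_v": "v", "tau_phi": "phi", "tau_gamma": "gamma", "tau_psi": "psi"}

    scales = {**_DEFAULT_SCALES, **dict(cfg.step_scales)}
    adapter = _Adapter(scales, cfg.adapt)
    acc_totals: dict[str, list[float]] = {k: [] for k in scales}

    n_keep = cfg.n_retained
    out = {
        "alpha": np.empty(n_keep),
        "beta": np.empty((n_keep, p)),
        "u": np.empty((n_keep, I)),
        "v": np.empty((n_keep, I)),
        "phi": np.empty((n_keep, T)),
        "gamma": np.empty((n_keep, T)),
        "psi": np.empty((n_keep, I, T)),
        "deviance": np.empty(n_keep),
    }
    tau_out = {name: np.empty(n_keep) for name in PRECISION_NAMES}
    binom_const = deviance_from_eta(np.zeros((I, T)), panel) / -2.0 - float(
        np.sum(-n * np.logaddexp(0.0, 0.0))
    )  # log C(n, y) summed
    max_res_v = 0.0
    max_res_g = 0.0

    def lp_alpha(a: float) -> float:
        if hp.alpha_precision <= 0:
            return 0.0
        return -0.5 * hp.alpha_precision * (a - hp.alpha_mean) ** 2

    # precompute the eigen-basis once for prior-only exact draws
    if cfg.prior_only:
        pass  # sample_icar recomputes; I is small and prior-only runs are cheap

    keep_idx = 0
    for it in range(cfg.n_iterations):
        in_burn = it < cfg.burn_in

        if cfg.prior_only:
            if "u" in terms:
                u = rng.standard_normal(I) / np.sqrt(tau["tau_u"])
            if "v" in terms:
                v = sample_icar(graph, tau["tau_v"], rng)
            if "phi" in terms:
                phi = rng.standard_normal(T) / np.sqrt(tau["tau_phi"])
            if "gamma" in terms:
                gam = sample_rw1(T, tau["tau_gamma"], rng)
            if "psi" in terms:
                psi = rng.standard_normal((I, T)) / np.sqrt(tau["tau_psi"])
        else:
            # ---- intercept
            s = adapter.scale("alpha")
            eps = s * rng.standard_normal()
            sp_new = _softplus(eta + eps)
            d = sum_y * eps - float(np.sum(n * (sp_new - sp))) + lp_alpha(alpha + eps) - lp_alpha(alpha)
            if np.log(rng.random()) < d:
                alpha += eps
                eta = eta + eps
                sp = sp_new
                acc = 1.0
            else:
                acc = 0.0
            adapter.record("alpha", acc)
            acc_totals["alpha"].append(acc) if not in_burn else None

            # ---- covariate coefficients
            if p:
                accs = []
                s = adapter.scale("beta")
                for j in range(p):
                    eps = s * rng.standard_normal()
                    xcol = X[:, :, j]
                    eta_new = eta + eps * xcol
                    sp_new = _softplus(eta_new)
                    d = eps * float(np.sum(y * xcol)) - float(np.sum(n * (sp_new - sp)))
                    if hp.beta_precision > 0:
                        d -= 0.5 * hp.beta_precision * (2.0 * beta[j] * eps + eps * eps)
                    if np.log(rng.random()) < d:
                        beta[j] += eps
                        eta = eta_new
                        sp = sp_new
                        accs.append(1.0)
                    else:
                        accs.append(0.0)
                rate = float(np.mean(accs))
                adapter.record("beta", rate)
                acc_totals["beta"].append(rate) if not in_burn else None

            # ---- beta <-> u exchange: an area-persistent covariate pattern
            # can be carried either by beta or by the unstructured spatial
            # effect; shifting mass between the two leaves eta almost
            # unchanged and is accepted mostly on the u prior, which breaks
            # the slow-mixing confounded direction.
            if p and "u" in terms:
                accs = []
                s = adapter.scale("beta_u")
                for j in range(p):
                    delta = s * rng.standard_normal()
                    xbar_j = xbar[:, j]
                    eta_new = eta + delta * (X[:, :, j] - xbar_j[:, None])
                    sp_new = _softplus(eta_new)
                    d = float(np.sum(y * (eta_new - eta) - n * (sp_new - sp)))
                    d += -0.5 * tau["tau_u"] * (
                        delta * delta * float(xbar_j @ xbar_j) - 2.0 * delta * float(u @ xbar_j)
                    )
                    if hp.beta_precision > 0:
                        d -= 0.5 * hp.beta_precision * (2.0 * beta[j] * delta + delta * delta)
                    if np.log(rng.random()) < d:
                        beta[j] += delta
                        u -= delta * xbar_j
                        eta = eta_new
                        sp = sp_new
                        accs.append(1.0)
                    else:
                        accs.append(0.0)
                rate = float(np.mean(accs))
                adapter.record("beta_u", rate)
                acc_totals["beta_u"].append(rate) if not in_burn else None

            # ---- unstructured spatial effect (parallel single-site)
            if "u" in terms:
                s = adapter.scale("u")
                eps = s * rng.standard_normal(I)
                eta_new = eta + eps[:, None]
                sp_new = _softplus(eta_new)
                dll = eps * row_y - np.sum(n * (sp_new - sp), axis=1)
                dpr = -0.5 * tau["tau_u"] * (2.0 * u * eps + eps * eps)
                accept = np.log(rng.random(I)) < dll + dpr
                u[accept] += eps[accept]
                eta[accept] = eta_new[accept]
                sp[accept] = sp_new[accept]
                rate = float(accept.mean())
                adapter.record("u", rate)
                acc_totals["u"].append(rate) if not in_burn else None

            # ---- structured spatial effect (ICAR)
            if "v" in terms:
                s = adapter.scale("v")
                if fast_v:
                    n_acc = 0
                    for cc in color_classes:
                        Wv = W @ v
                        eps = s * rng.standard_normal(cc.size)
                        eta_rows = eta[cc]
                        eta_new = eta_rows + eps[:, None]
                        sp_rows = sp[cc]
                        sp_new = _softplus(eta_new)
                        dll = eps * row_y[cc] - np.sum(n[cc] * (sp_new - sp_rows), axis=1)
                        dpr = -0.5 * tau["tau_v"] * (deg[cc] * eps * eps + 2.0 * eps * (deg[cc] * v[cc] - Wv[cc]))
                        accept = np.log(rng.random(cc.size)) < dll + dpr
                        idx = cc[accept]
                        v[idx] += eps[accept]
                        eta[idx] = eta_new[accept]
                        sp[idx] = sp_new[accept]
                        n_acc += int(accept.sum())
                    # exact re-centring absorbed by the (flat-prior) intercept
                    m = float(v.mean())
                    v -= m
                    alpha += m
                    rate = n_acc / I
                else:
                    n_acc = 0
                    for i in range(I):
                        ci = comp_of[i]
                        nc = comp_size[ci]
                        eps = s * float(rng.standard_normal())
                        shift = eps / nc
                        delta_rows = np.where(comp_of == ci, 0.0, shift)
                        delta_rows[i] = eps
                        eta_new = eta + delta_rows[:, None]
                        sp_new = _softplus(eta_new)
                        d = float(np.sum(y * delta_rows[:, None] - n * (sp_new - sp)))
                        nbr = graph.neighbors[i]
                        wv_i = float(v[list(nbr)].sum()) if nbr else 0.0
                        d += -0.5 * tau["tau_v"] * (deg[i] * eps * eps + 2.0 * eps * (deg[i] * v[i] - wv_i))
                        d += lp_alpha(alpha + shift) - lp_alpha(alpha)
                        if np.log(rng.random()) < d:
                            mask = comp_of == ci
                            v[mask] -= shift
                            v[i] += eps
                            alpha += shift
                            eta = eta_new
                            sp = sp_new
                            n_acc += 1
                    rate = n_acc / I
                adapter.record("v", rate)
                acc_totals["v"].append(rate) if not in_burn else None
                res = max(abs(float(v[comp].sum())) for comp in comps)
                max_res_v = max(max_res_v, res)

            # ---- unstructured temporal effect (parallel single-site)
            if "phi" in terms:
                s = adapter.scale("phi")
                eps = s * rng.standard_normal(T)
                eta_new = eta + eps[None, :]
                sp_new = _softplus(eta_new)
                dll = eps * col_y - np.sum(n * (sp_new - sp), axis=0)
                dpr = -0.5 * tau["tau_phi"] * (2.0 * phi * eps + eps * eps)
                accept = np.log(rng.random(T)) < dll + dpr
                phi[accept] += eps[accept]
                eta[:, accept] = eta_new[:, accept]
                sp[:, accept] = sp_new[:, accept]
                rate = float(accept.mean())
                adapter.record("phi", rate)
                acc_totals["phi"].append(rate) if not in_burn else None

            # ---- structured temporal trend (RW1, sequential composite moves)
            if "gamma" in terms:
                s = adapter.scale("gamma")
                n_acc = 0
                for t in range(T):
                    eps = s * float(rng.standard_normal())
                    col = eta[:, t]
                    sp_col = sp[:, t]
                    col_new = col + eps
                    sp_new = _softplus(col_new)
                    d = eps * col_y[t] - float(np.sum(n[:, t] * (sp_new - sp_col)))
                    tg = tau["tau_gamma"]
                    if t > 0:
                        d -= 0.5 * tg * (2.0 * (gam[t] - gam[t - 1]) * eps + eps * eps)
                    if t < T - 1:
                        d -= 0.5 * tg * (-2.0 * (gam[t + 1] - gam[t]) * eps + eps * eps)
                    shift = eps / T
                    d += lp_alpha(alpha + shift) - lp_alpha(alpha)
                    if np.log(rng.random()) < d:
                        gam -= shift
                        gam[t] += eps
                        alpha += shift
                        eta[:, t] = col_new
                        sp[:, t] = sp_new
                        n_acc += 1
                gam -= gam.mean()  # float-dust hygiene; exact-arithmetic no-op
                rate = n_acc / T
                adapter.record("gamma", rate)
                acc_totals["gamma"].append(rate) if not in_burn else None
                max_res_g = max(max_res_g, abs(float(gam.sum())))

            # ---- translation moves: shift mass between the intercept and the
            # mean of each proper iid effect block.  The likelihood only sees
            # alpha + effect, so these directions mix slowly under single-site
            # updates; the joint shift is accepted on the prior ratio alone.
            for term, vec, tau_name in (("u", u, "tau_u"), ("phi", phi, "tau_phi"), ("psi", psi, "tau_psi")):
                if term not in terms:
                    continue
                s = adapter.scale(f"shift_{term}")
                delta = s * rng.standard_normal()
                dim = vec.size
                d = -0.5 * tau[tau_name] * (dim * delta * delta - 2.0 * delta * float(vec.sum()))
                d += lp_alpha(alpha + delta) - lp_alpha(alpha)
                if np.log(rng.random()) < d:
                    alpha += delta
                    vec -= delta
                    acc = 1.0
                else:
                    acc = 0.0
                adapter.record(f"shift_{term}", acc)
                acc_totals[f"shift_{term}"].append(acc) if not in_burn else None

            # ---- space-time interaction (parallel single-cell)
            if "psi" in terms:
                s = adapter.scale("psi")
                eps = s * rng.standard_normal((I, T))
                eta_new = eta + eps
                sp_new = _softplus(eta_new)
                dll = y * eps - n * (sp_new - sp)
                dpr = -0.5 * tau["tau_psi"] * (2.0 * psi * eps + eps * eps)
                accept = np.log(rng.random((I, T))) < dll + dpr
                psi[accept] += eps[accept]
                eta[accept] = eta_new[accept]
                sp[accept] = sp_new[accept]
                rate = float(accept.mean())
                adapter.record("psi", rate)
                acc_totals["psi"].append(rate) if not in_burn else None

        # ---- joint scale moves along each block's variance-precision
        # funnel: (vec, tau) -> (c vec, tau / c^2).  The conditional prior
        # density is invariant under this map, so the acceptance ratio is the
        # likelihood change, the hyperprior ratio and a -2 log c Jacobian
        # term; without these moves the precision chains crawl when a block
        # is only weakly identified.
        if cfg.sample_precisions and not cfg.prior_only:
            for term, tau_name in (("u", "tau_u"), ("v", "tau_v"), ("phi", "tau_phi"),
                                   ("gamma", "tau_gamma"), ("psi", "tau_psi")):
                if term not in terms:
                    continue
                block = f"scale_{term}"
                s = adapter.scale(block)
                c = float(np.exp(s * rng.standard_normal()))
                vec = {"u": u, "v": v, "phi": phi, "gamma": gam, "psi": psi}[term]
                if term in ("u", "v"):
                    eta_new = eta + (c - 1.0) * vec[:, None]
                elif term in ("phi", "gamma"):
                    eta_new = eta + (c - 1.0) * vec[None, :]
                else:
                    eta_new = eta + (c - 1.0) * vec
                sp_new = _softplus(eta_new)
                tau_new = tau[tau_name] / (c * c)
                prior = hp.gamma_prior(tau_name)
                d = float(np.sum(y * (eta_new - eta) - n * (sp_new - sp)))
                d += -2.0 * np.log(c) + prior.logpdf(tau_new) - prior.logpdf(tau[tau_name])
                if np.log(rng.random()) < d:
                    vec *= c
                    # scaling preserves the sum-to-zero constraints in exact
                    # arithmetic; strip the amplified float residue
                    if term == "gamma":
                        vec -= vec.mean()
                    elif term == "v":
                        for comp in comps:
                            vec[comp] -= vec[comp].mean()
                    tau[tau_name] = tau_new
                    eta = eta_new
                    sp = sp_new
                    acc = 1.0
                else:
                    acc = 0.0
                adapter.record(block, acc)
                acc_totals[block].append(acc) if not in_burn else None

        # ---- precisions: conjugate Gibbs
        if cfg.sample_precisions:
            quads = {
                "tau_u": float(u @ u),
                "tau_v": float(np.sum((v[edges[:, 0]] - v[edges[:, 1]]) ** 2)) if edges.size else 0.0,
                "tau_phi": float(phi @ phi),
                "tau_gamma": float(np.sum(np.diff(gam) ** 2)),
                "tau_psi": float(np.sum(psi * psi)),
            }
            for name in PRECISION_NAMES:
                if term_of_tau[name] not in terms:
                    continue
                prior = hp.gamma_prior(name)
                shape = prior.shape + gibbs_shape[name]
                rate_ = prior.rate + 0.5 * quads[name]
                tau[name] = float(rng.gamma(shape, 1.0 / rate_))

        adapter.maybe_adapt(it, in_burn)

        if not in_burn and (it - cfg.burn_in) % cfg.thin == 0:
            out["alpha"][keep_idx] = alpha
            out["beta"][keep_idx] = beta
            out["u"][keep_idx] = u
            out["v"][keep_idx] = v
            out["phi"][keep_idx] = phi
            out["gamma"][keep_idx] = gam
            out["psi"][keep_idx] = psi
            for name in PRECISION_NAMES:
                tau_out[name][keep_idx] = tau[name]
            if cfg.prior_only:
                out["deviance"][keep_idx] = np.nan
            else:
                out["deviance"][keep_idx] = -2.0 * (binom_const + float(np.sum(y * eta - n * sp)))
            keep_idx += 1

    acceptance = {k: float(np.mean(r)) for k, r in acc_totals.items() if r}
    return PosteriorDraws(
        area_ids=graph.area_ids,
        beta_names=beta_names,
        alpha=out["alpha"][:keep_idx],
        beta=out["beta"][:keep_idx],
        u=out["u"][:keep_idx],
        v=out["v"][:keep_idx],
        phi=out["phi"][:keep_idx],
        gamma=out["gamma"][:keep_idx],
        psi=out["psi"][:keep_idx],
        tau={name: tau_out[name][:keep_idx] for name in PRECISION_NAMES},
        deviance=out["deviance"][:keep_idx],
        X=X,
        config=cfg,
        acceptance=acceptance,
        max_residual_v=max_res_v,
        max_residual_gamma=max_res_g,
    )


def summary_from_sample(sample: np.ndarray) -> PosteriorSummary:
    sample = np.asarray(sample, dtype=float)
    q2, q50, q97 = np.percentile(sample, [2.5, 50.0, 97.5])
    return PosteriorSummary(
        mean=float(sample.mean()),
        sd=float(sample.std(ddof=1)) if sample.size > 1 else 0.0,
        q2_5=float(q2),
        q50=float(q50),
        q97_5=float(q97),
    )


def _resolve_selector(draws: PosteriorDraws, selector: str) -> np.ndarray:
    """Map a quantity name like ``alpha``, ``beta[cov1]`` or ``theta[3,1]``
    to its vector of retained draws."""
    sel = selector.strip()
    if sel in ("alpha", "deviance"):
        return getattr(draws, sel)
    if sel in PRECISION_NAMES:
        return draws.tau[sel]
    if "[" in sel and sel.endswith("]"):
        base, arg = sel[:-1].split("[", 1)
        base = base.strip()
        if base == "beta":
            if arg in draws.beta_names:
                return draws.beta[:, draws.beta_names.index(arg)]
            return draws.beta[:, int(arg)]
        if base in ("u", "v"):
            arr = getattr(draws, base)
            idx = draws.area_ids.index(arg) if arg in draws.area_ids else int(arg)
            return arr[:, idx]
        if base in ("phi", "gamma"):
            return getattr(draws, base)[:, int(arg)]
        if base in ("psi", "theta", "eta"):
            i_s, t_s = arg.split(",")
            i = draws.area_ids.index(i_s.strip()) if i_s.strip() in draws.area_ids else int(i_s)
            t = int(t_s)
            if base == "psi":
                return draws.psi[:, i, t]
            eta = draws.eta_draws()[:, i, t]
            return expit(eta) if base == "theta" else eta
    raise KeyError(f"unknown posterior quantity {selector!r}")


def summarize(draws: PosteriorDraws, selector: str, min_draws: int = 100) -> PosteriorSummary:
    """Posterior mean, sd and central 95% credible interval of one quantity."""
    if draws.n_draws < min_draws:
        raise ModelError(f"need at least {min_draws} retained draws, have {draws.n_draws}")
    return summary_from_sample(_resolve_selector(draws, selector))


def odds_ratio_summary(draws: PosteriorDraws, covariate: str, min_draws: int = 100) -> PosteriorSummary:
    """Odds ratio of a covariate: posterior mean of exp(beta) with 95% CI.

    The ``significant`` flag marks credible intervals that exclude 1.
    """
    if covariate not in draws.beta_names:
        raise KeyError(f"covariate {covariate!r} is not in the model")
    if draws.n_draws < min_draws:
        raise ModelError(f"need at least {min_draws} retained draws, have {draws.n_draws}")
    or_draws = np.exp(draws.beta[:, draws.beta_names.index(covariate)])
    s = summary_from_sample(or_draws)
    return PosteriorSummary(
        mean=s.mean,
        sd=s.sd,
        q2_5=s.q2_5,
        q50=s.q50,
        q97_5=s.q97_5,
        significant=not (s.q2_5 <= 1.0 <= s.q97_5),
    )


def effect_surfaces(draws: PosteriorDraws) -> dict[str, np.ndarray]:
    """Posterior-mean odds-ratio surfaces of the random effects.

    Exponentiation happens per draw and is then averaged (the mean of
    ``exp(x)`` is not ``exp(mean(x))``), giving per-area, per-period and
    per-cell odds ratios relative to the intercept, ready for quantile
    classification:

    - ``"spatial"``: combined heterogeneity ``exp(u_i + v_i)``, length I
    - ``"temporal_unstructured"``: ``exp(phi_t)``, length T
    - ``"temporal_structured"``: ``exp(gamma_t)``, length T
    - ``"interaction"``: ``exp(psi_it)``, shape I x T
    """
    return {
        "spatial": np.exp(draws.u + draws.v).mean(axis=0),
        "temporal_unstructured": np.exp(draws.phi).mean(axis=0),
        "temporal_structured": np.exp(draws.gamma).mean(axis=0),
        "interaction": np.exp(draws.psi).mean(axis=0),
    }
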