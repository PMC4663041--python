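"""DIC computation and covariate selection.

Model comparison uses the deviance information criterion
``DIC = Dbar + pD`` with ``pD = Dbar - Dhat``: ``Dbar`` is the posterior
mean deviance and ``Dhat`` the deviance at the posterior mean of the linear
predictor (the plug-in is taken on the eta scale, the convention for latent
Gaussian models).  Smaller DIC means better fit.  The selection procedure
mirrors ecological-regression practice: every candidate covariate is first
fitted separately on top of the full spatio-temporal model and ranked by
DIC; a multivariable model is then built by greedily including candidates
in rank order for as long as the DIC keeps dropping.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .graph import AreaGraph
from .model import HyperpriorSpec, ModelError, deviance_from_eta
from .mcmc import McmcConfig, PosteriorDraws, PosteriorSummary, odds_ratio_summary, run_mcmc
from .prep import CovariateTable, PanelData

__all__ = [
    "DICResult",
    "ScreenEntry",
    "SelectionTrace",
    "compute_dic",
    "univariable_screen",
    "forward_select",
]


@dataclass(frozen=True)
class DICResult:
    dbar: float
    dhat: float
    pd: float
    dic: float


@dataclass(frozen=True)
class ScreenEntry:
    name: str
    dic: DICResult
    odds_ratio: PosteriorSummary
    rank: int


@dataclass(frozen=True)
class SelectionStep:
    candidate: str
    dic: DICResult
    accepted: bool


@dataclass(frozen=True)
class SelectionTrace:
    baseline: DICResult
    steps: tuple[SelectionStep, ...]


def compute_dic(draws: PosteriorDraws, panel: PanelData, min_draws: int = 100) -> DICResult:
    """DIC from retained draws: Dbar, eta-scale plug-in Dhat, pD and DIC."""
    if draws.n_draws < min_draws:
        raise ModelError(f"DIC needs at least {min_draws} retained draws, have {draws.n_draws}")
    if not np.all(np.isfinite(draws.deviance)):
        raise ModelError("stored deviances are not finite (prior-only run?)")
    dbar = float(draws.deviance.mean())
    eta_mean = draws.eta_draws().mean(axis=0)
    dhat = deviance_from_eta(eta_mean, panel)
    pd = dbar - dhat
    return DICResult(dbar=dbar, dhat=dhat, pd=pd, dic=dbar + pd)


def _candidate_seed(master_seed: int, label: str) -> int:
    """Deterministic per-candidate seed from the master seed and a name."""
    return int((master_seed * 2654435761 + zlib.crc32(label.encode())) % 2**31)


def _fit(
    panel: PanelData,
    graph: AreaGraph,
    hp: HyperpriorSpec,
    cfg: McmcConfig,
    cov: CovariateTable,
    names: tuple[str, ...],
    seed_label: str,
) -> PosteriorDraws:
    X = cov.design_matrix(names) if names else None
    cfg_run = replace(cfg, seed=_candidate_seed(cfg.seed, seed_label))
    return run_mcmc(panel, graph, hp, cfg_run, X=X, beta_names=names or None)


def univariable_screen(
    panel: PanelData,
    graph: AreaGraph,
    hp: HyperpriorSpec,
    cfg: McmcConfig,
    cov: CovariateTable,
    candidates: list[str] | tuple[str, ...] | None = None,
) -> tuple[list[ScreenEntry], DICResult]:
    """Fit each candidate covariate separately and rank by ascending DIC.

    Every fit uses identical chain settings (so DIC differences are
    comparable) and a fixed per-candidate seed derived from the master seed
    and the covariate name.  Returns the ranked entries and the DIC of the
    covariate-free baseline model.
    """
    if candidates is None:
        candidates = list(cov.names)
    for name in candidates:
        cov.column_index(name)  # raises on unknown candidates
    baseline_draws = _fit(panel, graph, hp, cfg, cov, (), "baseline")
    baseline = compute_dic(baseline_draws, panel)
    results = []
    for name in candidates:
        draws = _fit(panel, graph, hp, cfg, cov, (name,), f"uni:{name}")
        results.append((name, compute_dic(draws, panel), odds_ratio_summary(draws, name)))
    results.sort(key=lambda r: r[1].dic)
    ranked = [
        ScreenEntry(name=name, dic=dic, odds_ratio=orr, rank=k + 1)
        for k, (name, dic, orr) in enumerate(results)
    ]
    return ranked, baseline


def forward_select(
    ranked: list[ScreenEntry],
    panel: PanelData,
    graph: AreaGraph,
    hp: HyperpriorSpec,
    cfg: McmcConfig,
    cov: CovariateTable,
    baseline: DICResult | None = None,
    dic_tolerance: float = 0.0,
) -> tuple[tuple[str, ...], PosteriorDraws, SelectionTrace]:
    """Greedy forward inclusion in univariable rank order.

    Starting from the covariate-free model, candidates are tried in rank
    order; one is kept only if it lowers the current DIC by more than
    ``dic_tolerance``, and selection stops at the first candidate that does
    not (the DIC can be "no further reduced").  A small positive tolerance
    (1-2) guards against pure Monte Carlo wiggle in the DIC.  Returns the
    selected names, the final fit, and the trial-by-trial trace.
    """
    if not ranked:
        raise ModelError("ranked candidate list is empty")
    if baseline is None:
        baseline_draws = _fit(panel, graph, hp, cfg, cov, (), "baseline")
        baseline = compute_dic(baseline_draws, panel)
    selected: list[str] = []
    current_dic = baseline.dic
    best_draws: PosteriorDraws | None = None
    steps: list[SelectionStep] = []
    for entry in ranked:
        trial = tuple(selected + [entry.name])
        draws = _fit(panel, graph, hp, cfg, cov, trial, "fwd:" + "+".join(trial))
        dic = compute_dic(draws, panel)
        accepted = dic.dic < current_dic - dic_tolerance
        steps.append(SelectionStep(candidate=entry.name, dic=dic, accepted=accepted))
        if accepted:
            selected.append(entry.name)
            current_dic = dic.dic
            best_draws = draws
        else:
            break
    if best_draws is None:
        best_draws = _fit(panel, graph, hp, cfg, cov, (), "final:baseline")
    return tuple(selected), best_draws, SelectionTrace(baseline=baseline, steps=tuple(steps))
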