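"""Quantile classification of effect surfaces and pipeline exports.

Posterior odds-ratio surfaces are mapped to ordinal classes at their
empirical quantile breaks, the standard choropleth convention in disease
mapping.  Exports are plain CSV (rates, classified surfaces, an OR table in
the usual variable / OR / CI / DIC layout), an optional GeoJSON with
per-feature properties when a geometry file is supplied, and a JSON
metadata sidecar recording seed, configuration, acceptance rates and
constraint residuals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws, effect_surfaces, odds_ratio_summary
from .prep import PanelData
from .selection import DICResult, SelectionTrace

__all__ = [
    "ClassifiedSurface",
    "quantile_classify",
    "nonattendance_odds_increase",
    "export_report",
    "selection_table",
]


@dataclass(frozen=True)
class ClassifiedSurface:
    values: np.ndarray
    class_index: np.ndarray
    class_breaks: np.ndarray
    k: int
    warnings: tuple[str, ...] = field(default_factory=tuple)


def quantile_classify(values: np.ndarray, k: int = 5) -> ClassifiedSurface:
    """Assign each value to one of ``k`` quantile classes.

    Breaks sit at the ``j/k`` empirical quantiles; a value exactly on a
    break goes to the lower class, which makes the classification invariant
    under strictly monotone transforms.  Fewer distinct values than classes
    yields a degenerate classification, flagged in ``warnings``.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot classify an empty surface")
    if k < 2:
        raise ValueError("need at least two classes")
    breaks = np.quantile(values, np.arange(1, k) / k)
    classes = np.searchsorted(breaks, values, side="left")
    warnings: tuple[str, ...] = ()
    if len(np.unique(values)) < k:
        warnings = (f"only {len(np.unique(values))} distinct values for {k} classes; classification degenerate",)
    return ClassifiedSurface(values=values, class_index=classes, class_breaks=breaks, k=k, warnings=warnings)


def nonattendance_odds_increase(or_attendance: float) -> float:
    """Percent increase in the odds of *non*-attendance implied by an
    attendance odds ratio below one.

    An attendance OR of 0.94 for areas above the covariate median means the
    odds of staying away are 1/0.94 = 1.064 times higher there, a 6%
    increase.
    """
    if or_attendance <= 0:
        raise ValueError("odds ratio must be positive")
    return (1.0 / or_attendance - 1.0) * 100.0


def selection_table(trace: SelectionTrace, screen_entries=None) -> pd.DataFrame:
    """Selection results in the usual reporting layout:
    variable, OR, CI bounds, DIC, rank."""
    rows = []
    if screen_entries:
        for e in screen_entries:
            rows.append(
                {
                    "variable": e.name,
                    "odds_ratio": e.odds_ratio.mean,
                    "ci_2.5": e.odds_ratio.q2_5,
                    "ci_97.5": e.odds_ratio.q97_5,
                    "dic": e.dic.dic,
                    "rank": e.rank,
                }
            )
    rows.append(
        {
            "variable": "(baseline, no covariates)",
            "odds_ratio": np.nan,
            "ci_2.5": np.nan,
            "ci_97.5": np.nan,
            "dic": trace.baseline.dic,
            "rank": np.nan,
        }
    )
    return pd.DataFrame(rows, columns=["variable", "odds_ratio", "ci_2.5", "ci_97.5", "dic", "rank"])


def _or_table(draws: PosteriorDraws, dic: DICResult | None) -> pd.DataFrame:
    rows = []
    for name in draws.beta_names:
        s = odds_ratio_summary(draws, name)
        rows.append(
            {
                "variable": name,
                "odds_ratio": s.mean,
                "ci_2.5": s.q2_5,
                "ci_97.5": s.q97_5,
                "dic": dic.dic if dic is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["variable", "odds_ratio", "ci_2.5", "ci_97.5", "dic"])


def export_report(
    draws: PosteriorDraws,
    panel: PanelData,
    out_dir: str | Path,
    dic: DICResult | None = None,
    k_classes: int = 5,
    geometry: str | Path | None = None,
) -> dict[str, Path]:
    """Write the standard result files for one fitted model.

    Produces ``rates.csv`` (observed rates per area and period),
    ``surface_*.csv`` (posterior-mean odds-ratio surfaces with quantile
    class indices), ``or_table.csv``, ``run_metadata.json`` and, when a
    GeoJSON geometry is given, ``surfaces.geojson`` with the per-area
    results attached as feature properties (features are matched on an
    ``area_id`` property).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    written: dict[str, Path] = {}
    rates = panel.to_frame()
    rates["rate"] = rates["participants"] / rates["population"]
    path = out_dir / "rates.csv"
    rates.to_csv(path, index=False)
    written["rates"] = path

    surfaces = effect_surfaces(draws)
    spatial = surfaces["spatial"]
    cls = quantile_classify(spatial, k_classes)
    df = pd.DataFrame({"area_id": draws.area_ids, "or_spatial": spatial, "class": cls.class_index})
    path = out_dir / "surface_spatial.csv"
    df.to_csv(path, index=False)
    written["surface_spatial"] = path

    inter = surfaces["interaction"]
    cls_i = quantile_classify(inter.ravel(), k_classes)
    i_idx, t_idx = np.meshgrid(np.arange(len(draws.area_ids)), np.arange(draws.n_periods), indexing="ij")
    df = pd.DataFrame(
        {
            "area_id": np.asarray(draws.area_ids)[i_idx.ravel()],
            "period": t_idx.ravel() + 1,
            "or_interaction": inter.ravel(),
            "class": cls_i.class_index,
        }
    )
    path = out_dir / "surface_interaction.csv"
    df.to_csv(path, index=False)
    written["surface_interaction"] = path

    df = pd.DataFrame(
        {
            "period": np.arange(draws.n_periods) + 1,
            "or_temporal_unstructured": surfaces["temporal_unstructured"],
            "or_temporal_structured": surfaces["temporal_structured"],
        }
    )
    path = out_dir / "surface_temporal.csv"
    df.to_csv(path, index=False)
    written["surface_temporal"] = path

    path = out_dir / "or_table.csv"
    _or_table(draws, dic).to_csv(path, index=False)
    written["or_table"] = path

    meta = {
        "seed": draws.config.seed,
        "config": {
            "n_iterations": draws.config.n_iterations,
            "burn_in": draws.config.burn_in,
            "thin": draws.config.thin,
            "terms": list(draws.config.terms),
        },
        "acceptance_rates": draws.acceptance,
        "max_residual_v": draws.max_residual_v,
        "max_residual_gamma": draws.max_residual_gamma,
        "n_retained_draws": draws.n_draws,
        "dic": None if dic is None else {"dbar": dic.dbar, "dhat": dic.dhat, "pd": dic.pd, "dic": dic.dic},
    }
    path = out_dir / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2))
    written["metadata"] = path

    if geometry is not None:
        geo = json.loads(Path(geometry).read_text())
        if geo.get("type") != "FeatureCollection":
            raise ValueError("geometry file must be a GeoJSON FeatureCollection")
        by_area = {a: (spatial[i], int(cls.class_index[i])) for i, a in enumerate(draws.area_ids)}
        last_rates = panel.rates()[:, -1]
        rate_by_area = {a: float(last_rates[i]) for i, a in enumerate(draws.area_ids)}
        for feature in geo.get("features", []):
            props = feature.setdefault("properties", {})
            area = props.get("area_id")
            if area in by_area:
                props["or_spatial"], props["spatial_class"] = by_area[area]
                props["rate_last_period"] = rate_by_area[area]
        path = out_dir / "surfaces.geojson"
        path.write_text(json.dumps(geo))
        written["geojson"] = path

    return written
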