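"""Panel construction and covariate pre-processing.

The analysis panel holds, per area and biennial period, the participant
count ``Y_it`` and the eligible female population ``n_it`` (counts summed
over the two years of a period, population averaged over them).  Area-level
covariates are screened for collinearity on their continuous values and then
dichotomized at their per-period cross-area medians, mirroring common
practice in ecological regression on administrative social-structure data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelData",
    "CovariateTable",
    "PanelError",
    "ScreenRecord",
    "ScreenResult",
    "build_panel",
    "dichotomize_at_median",
    "correlation_screen",
]


class PanelError(ValueError):
    """Invalid or incomplete panel input."""


@dataclass(frozen=True)
class PanelData:
    """Complete I x T grid of participant counts and populations.

    ``y[i, t]`` is the participant count, ``n[i, t]`` the averaged eligible
    female population of area ``i`` in period ``t``.  Periods are indexed
    ``0 .. T-1`` in chronological order.
    """

    area_ids: tuple[str, ...]
    y: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        n = np.asarray(self.n, dtype=float)
        if y.ndim != 2 or y.shape != n.shape:
            raise PanelError(f"y and n must be matching I x T arrays, got {y.shape} / {n.shape}")
        if y.shape[0] != len(self.area_ids):
            raise PanelError("first axis must match the number of areas")
        if np.any(n <= 0):
            raise PanelError("populations must be positive")
        if np.any(y < 0):
            raise PanelError("participant counts must be non-negative")
        bad = np.argwhere(y > np.round(n))
        if bad.size:
            i, t = bad[0]
            raise PanelError(
                f"participants exceed population for area {self.area_ids[i]!r}, "
                f"period {t + 1}: {y[i, t]:g} > {n[i, t]:g}"
            )
        if not np.allclose(y, np.round(y)):
            raise PanelError("participant counts must be integers")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "n", n)

    @property
    def n_areas(self) -> int:
        return self.y.shape[0]

    @property
    def n_periods(self) -> int:
        return self.y.shape[1]

    def rates(self) -> np.ndarray:
        """Participation rates ``Y / n`` per cell."""
        return self.y / self.n

    def overall_rates(self) -> np.ndarray:
        """Pooled participation rate per period."""
        return self.y.sum(axis=0) / self.n.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        i, t = np.meshgrid(np.arange(self.n_areas), np.arange(self.n_periods), indexing="ij")
        return pd.DataFrame(
            {
                "area_id": np.asarray(self.area_ids)[i.ravel()],
                "period": t.ravel() + 1,
                "participants": self.y.ravel().astype(int),
                "population": self.n.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, area_ids: Sequence[str] | None = None) -> "PanelData":
        required = {"area_id", "period", "participants", "population"}
        if not required.issubset(df.columns):
            raise PanelError(f"panel table needs columns {sorted(required)}")
        if area_ids is None:
            area_ids = list(dict.fromkeys(df["area_id"].astype(str)))
        periods = sorted(df["period"].unique())
        wide_y = df.pivot_table(index="area_id", columns="period", values="participants", aggfunc="sum")
        wide_n = df.pivot_table(index="area_id", columns="period", values="population", aggfunc="mean")
        missing = [a for a in area_ids if a not in wide_y.index]
        if missing:
            raise PanelError(f"areas missing from panel table: {missing[:5]}")
        if wide_y.isna().any().any() or wide_n.isna().any().any():
            cell = np.argwhere(wide_y.isna().to_numpy())
            raise PanelError(f"incomplete area x period grid (first missing cell {cell[:1]})")
        y = wide_y.loc[list(area_ids), periods].to_numpy()
        n = wide_n.loc[list(area_ids), periods].to_numpy()
        return cls(tuple(str(a) for a in area_ids), y, n)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, area_ids: Sequence[str] | None = None) -> "PanelData":
        return cls.from_frame(pd.read_csv(path, dtype={"area_id": str}), area_ids)


@dataclass(frozen=True)
class ScreenRecord:
    name: str
    partner: str | None
    r: float | None
    reason: str  # "correlated" or "constant"


@dataclass(frozen=True)
class ScreenResult:
    retained: tuple[str, ...]
    excluded: tuple[ScreenRecord, ...]


@dataclass(frozen=True)
class CovariateTable:
    """Named area x period covariates, continuous with an optional binary view.

    ``values`` has shape ``(I, T, p)``.  After :func:`dichotomize_at_median`,
    ``binary`` holds the {0,1} median-split view and ``medians`` the
    per-covariate, per-period cut points (shape ``(p, T)``).
    """

    area_ids: tuple[str, ...]
    names: tuple[str, ...]
    values: np.ndarray
    binary: np.ndarray | None = None
    medians: np.ndarray | None = None
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise PanelError("covariate values must have shape (areas, periods, covariates)")
        if values.shape[0] != len(self.area_ids) or values.shape[2] != len(self.names):
            raise PanelError("covariate array shape inconsistent with area_ids / names")
        if len(set(self.names)) != len(self.names):
            raise PanelError("covariate names must be unique")
        object.__setattr__(self, "values", values)

    @property
    def n_areas(self) -> int:
        return self.values.shape[0]

    @property
    def n_periods(self) -> int:
        return self.values.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[2]

    def column_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown covariate {name!r}") from None

    def subset(self, names: Iterable[str]) -> "CovariateTable":
        idx = [self.column_index(n) for n in names]
        return CovariateTable(
            self.area_ids,
            tuple(self.names[j] for j in idx),
            self.values[:, :, idx],
            None if self.binary is None else self.binary[:, :, idx],
            None if self.medians is None else self.medians[idx],
            self.warnings,
        )

    def design_matrix(self, names: Iterable[str] | None = None, centered: bool = True) -> np.ndarray:
        """Model design array ``(I, T, k)`` from the dichotomized view.

        Columns are centred by default (a shift that leaves the covariate
        coefficient and its odds ratio unchanged but keeps the intercept
        interpretable as the overall participation level).
        """
        if self.binary is None:
            raise PanelError("dichotomize_at_median must run before building a design matrix")
        if names is None:
            names = self.names
        idx = [self.column_index(n) for n in names]
        X = self.binary[:, :, idx].astype(float)
        if centered:
            X = X - X.mean(axis=(0, 1), keepdims=True)
        return X

    def to_frame(self, view: str = "values") -> pd.DataFrame:
        arr = {"values": self.values, "binary": self.binary}[view]
        if arr is None:
            raise PanelError("no dichotomized view available")
        i, t = np.meshgrid(np.arange(self.n_areas), np.arange(self.n_periods), indexing="ij")
        df = pd.DataFrame({"area_id": np.asarray(self.area_ids)[i.ravel()], "period": t.ravel() + 1})
        for k, name in enumerate(self.names):
            df[name] = arr[:, :, k].ravel()
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, area_ids: Sequence[str] | None = None) -> "CovariateTable":
        if not {"area_id", "period"}.issubset(df.columns):
            raise PanelError("covariate table needs 'area_id' and 'period' columns")
        names = [c for c in df.columns if c not in ("area_id", "period")]
        if area_ids is None:
            area_ids = list(dict.fromkeys(df["area_id"].astype(str)))
        periods = sorted(df["period"].unique())
        blocks = []
        for name in names:
            wide = df.pivot_table(index="area_id", columns="period", values=name, aggfunc="mean")
            if wide.isna().any().any():
                raise PanelError(f"covariate {name!r} has missing area x period cells")
            blocks.append(wide.loc[list(area_ids), periods].to_numpy())
        values = np.stack(blocks, axis=2) if blocks else np.empty((len(area_ids), len(periods), 0))
        return cls(tuple(str(a) for a in area_ids), tuple(names), values)

    def write_csv(self, path: str | Path, view: str = "values") -> None:
        self.to_frame(view).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, area_ids: Sequence[str] | None = None) -> "CovariateTable":
        return cls.from_frame(pd.read_csv(path, dtype={"area_id": str}), area_ids)


def build_panel(
    counts_by_year: pd.DataFrame,
    population_by_year: pd.DataFrame,
    period_map: Mapping[int, int],
    area_ids: Sequence[str] | None = None,
) -> PanelData:
    """Aggregate yearly counts into biennial periods.

    Participants are summed over each period's two years; the population is
    the arithmetic mean over them.  ``period_map`` maps calendar year to
    period index (1-based); every period must cover exactly two years.
    Missing (area, year) cells are rejected with the offending key.
    """
    years_per_period: dict[int, list[int]] = {}
    for year, period in period_map.items():
        years_per_period.setdefault(int(period), []).append(int(year))
    for period, years in sorted(years_per_period.items()):
        if len(years) != 2:
            raise PanelError(f"period {period} maps {len(years)} years, expected exactly 2")

    def _wide(df: pd.DataFrame, value: str) -> pd.DataFrame:
        required = {"area_id", "year", value}
        if not required.issubset(df.columns):
            raise PanelError(f"yearly table needs columns {sorted(required)}")
        return df.pivot_table(index="area_id", columns="year", values=value, aggfunc="sum")

    counts = _wide(counts_by_year, "participants")
    pops = _wide(population_by_year, "population")
    if area_ids is None:
        area_ids = list(dict.fromkeys(counts_by_year["area_id"].astype(str)))
    for table, label in ((counts, "participants"), (pops, "population")):
        for area in area_ids:
            if area not in table.index:
                raise PanelError(f"missing {label} rows for area {area!r}")
        for year in period_map:
            if year not in table.columns:
                raise PanelError(f"missing {label} column for year {year}")
            nulls = table.loc[list(area_ids), year].isna()
            if nulls.any():
                raise PanelError(f"missing {label} cell ({nulls.idxmax()!r}, {year})")

    periods = sorted(years_per_period)
    y = np.column_stack(
        [counts.loc[list(area_ids), years_per_period[p]].sum(axis=1).to_numpy() for p in periods]
    )
    n = np.column_stack(
        [pops.loc[list(area_ids), years_per_period[p]].mean(axis=1).to_numpy() for p in periods]
    )
    return PanelData(tuple(str(a) for a in area_ids), y, n)


def dichotomize_at_median(cov: CovariateTable) -> CovariateTable:
    """Median-split every covariate within each period.

    A value strictly above that period's cross-area median codes 1, anything
    at or below it codes 0 (ties go low).  The split is per period because
    the covariates are measured anew each period.  All-constant columns
    dichotomize to zeros and are flagged in ``warnings``.
    """
    medians = np.median(cov.values, axis=0).T  # (p, T)
    binary = (cov.values > medians.T[None, :, :]).astype(float)
    warnings = list(cov.warnings)
    for k, name in enumerate(cov.names):
        for t in range(cov.n_periods):
            col = cov.values[:, t, k]
            if np.all(col == col[0]):
                warnings.append(f"covariate {name!r} is constant in period {t + 1}; coded all-zero")
    return replace(cov, binary=binary, medians=medians, warnings=tuple(warnings))


def correlation_screen(cov: CovariateTable, threshold: float = 0.8) -> ScreenResult:
    """Exclude collinear covariates from the candidate set.

    Pearson correlations are computed on the pooled continuous values
    (areas x periods stacked).  Scanning in input order, a covariate is
    dropped when its absolute correlation with any already-retained one
    exceeds ``threshold`` — the later-listed member of a pair loses.
    Constant columns have no defined correlation and are excluded outright.
    """
    if cov.n_covariates < 2:
        raise PanelError("correlation screening needs at least two covariates")
    pooled = cov.values.reshape(-1, cov.n_covariates)
    retained: list[int] = []
    excluded: list[ScreenRecord] = []
    for j, name in enumerate(cov.names):
        col = pooled[:, j]
        if np.std(col) == 0:
            excluded.append(ScreenRecord(name, None, None, "constant"))
            continue
        hit = None
        for k in retained:
            r = float(np.corrcoef(pooled[:, k], col)[0, 1])
            if abs(r) > threshold:
                hit = ScreenRecord(name, cov.names[k], r, "correlated")
                break
        if hit is None:
            retained.append(j)
        else:
            excluded.append(hit)
    return ScreenResult(tuple(cov.names[j] for j in retained), tuple(excluded))
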