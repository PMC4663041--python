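import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from stscreen.prep import (
    CovariateTable,
    PanelData,
    PanelError,
    build_panel,
    correlation_screen,
    dichotomize_at_median,
)


def yearly_frames(rows):
    """rows: (area, year, participants, population)"""
    df = pd.DataFrame(rows, columns=["area_id", "year", "participants", "population"])
    return df[["area_id", "year", "participants"]], df[["area_id", "year", "population"]]


class TestBuildPanel:
    def test_counts_summed_population_averaged(self):
        counts, pops = yearly_frames([("A", 2007, 500, 2000), ("A", 2008, 480, 2000)])
        panel = build_panel(counts, pops, {2007: 1, 2008: 1})
        assert panel.y[0, 0] == 980
        assert panel.n[0, 0] == 2000
        assert panel.rates()[0, 0] == pytest.approx(0.49)

    def test_population_mean_of_two_years(self):
        counts, pops = yearly_frames([("A", 2007, 100, 1900), ("A", 2008, 100, 2100)])
        panel = build_panel(counts, pops, {2007: 1, 2008: 1})
        assert panel.n[0, 0] == 2000

    def test_participants_exceeding_average_population_rejected(self):
        counts, pops = yearly_frames([("A", 2007, 1500, 2000), ("A", 2008, 1500, 2000)])
        with pytest.raises(PanelError, match="exceed"):
            build_panel(counts, pops, {2007: 1, 2008: 1})

    def test_missing_cell_names_the_key(self):
        counts, pops = yearly_frames([("A", 2007, 10, 100), ("A", 2008, 10, 100),
                                      ("B", 2007, 10, 100)])
        with pytest.raises(PanelError, match="2008"):
            build_panel(counts, pops, {2007: 1, 2008: 1})

    def test_period_must_cover_two_years(self):
        counts, pops = yearly_frames([("A", 2007, 10, 100)])
        with pytest.raises(PanelError, match="expected exactly 2"):
            build_panel(counts, pops, {2007: 1})

    def test_year_order_within_period_is_irrelevant(self):
        rows = [("A", 2007, 300, 1000), ("A", 2008, 200, 1200),
                ("B", 2007, 100, 900), ("B", 2008, 150, 800)]
        counts, pops = yearly_frames(rows)
        counts_rev, pops_rev = yearly_frames(rows[::-1])
        a = build_panel(counts, pops, {2007: 1, 2008: 1})
        b = build_panel(counts_rev, pops_rev, {2007: 1, 2008: 1}, area_ids=a.area_ids)
        assert np.array_equal(a.y, b.y) and np.array_equal(a.n, b.n)


def cov_table(columns, n_periods=1):
    """columns: dict name -> (I,) or (I, T) array of continuous values."""
    names = tuple(columns)
    arrays = []
    for name in names:
        arr = np.asarray(columns[name], dtype=float)
        if arr.ndim == 1:
            arr = np.repeat(arr[:, None], n_periods, axis=1)
        arrays.append(arr)
    values = np.stack(arrays, axis=2)
    ids = tuple(f"a{i}" for i in range(values.shape[0]))
    return CovariateTable(ids, names, values)


class TestDichotomize:
    def test_odd_count_strictly_above_median(self):
        cov = dichotomize_at_median(cov_table({"x": [1, 2, 3, 4, 5]}))
        assert np.array_equal(cov.binary[:, 0, 0], [0, 0, 0, 1, 1])
        assert cov.medians[0, 0] == 3

    def test_even_count_interpolated_median(self):
        cov = dichotomize_at_median(cov_table({"x": [1, 2, 3, 4]}))
        assert cov.medians[0, 0] == 2.5
        assert np.array_equal(cov.binary[:, 0, 0], [0, 0, 1, 1])

    def test_split_is_per_period(self):
        # medians 48.2, 48.4, 50.1 across periods: a constant 49 flips coding
        values = np.array(
            [
                [47.0, 47.0, 48.0],
                [48.0, 48.0, 51.0],
                [48.2, 48.4, 50.1],
                [49.0, 49.0, 49.0],
                [50.0, 50.0, 52.0],
            ]
        )[:, :, None]
        cov = CovariateTable(tuple("abcde"), ("employment",), values)
        cov = dichotomize_at_median(cov)
        assert list(cov.medians[0]) == [48.2, 48.4, 50.1]
        assert list(cov.binary[3, :, 0]) == [1, 1, 0]

    def test_value_at_median_codes_low(self):
        cov = dichotomize_at_median(cov_table({"x": [1, 2, 3]}))
        assert cov.binary[1, 0, 0] == 0

    def test_constant_column_warns_and_codes_zero(self):
        cov = dichotomize_at_median(cov_table({"x": [2, 2, 2]}))
        assert np.all(cov.binary == 0)
        assert any("constant" in w for w in cov.warnings)

    @given(hst.lists(hst.floats(-1e6, 1e6), min_size=3, max_size=20, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, values):
        base = dichotomize_at_median(cov_table({"x": values}))
        # strictly monotone map: affine-exp blend preserves order
        transformed = dichotomize_at_median(
            cov_table({"x": [3.0 * v + np.arctan(v / 1e6) for v in values]})
        )
        assert np.array_equal(base.binary, transformed.binary)


class TestCorrelationScreen:
    def test_perfectly_collinear_pair_drops_the_later(self, rng):
        x = rng.standard_normal(50)
        res = correlation_screen(cov_table({"x": x, "double_x": 2 * x}))
        assert res.retained == ("x",)
        assert res.excluded[0].name == "double_x"
        assert res.excluded[0].partner == "x"
        assert res.excluded[0].r == pytest.approx(1.0)

    def test_independent_noise_all_retained(self, rng):
        cols = {f"c{i}": rng.standard_normal(2000) for i in range(4)}
        res = correlation_screen(cov_table(cols))
        assert res.retained == tuple(cols)

    def test_near_duplicate_dropped_unrelated_kept(self, rng):
        x = rng.standard_normal(200)
        z = rng.standard_normal(200)
        res = correlation_screen(cov_table({"x": x, "x_noisy": x + 1e-3 * rng.standard_normal(200), "z": z}))
        assert res.retained == ("x", "z")
        assert abs(res.excluded[0].r) > 0.99

    def test_threshold_above_one_retains_everything(self, rng):
        x = rng.standard_normal(30)
        res = correlation_screen(cov_table({"x": x, "y": 2 * x}), threshold=1.0 + 1e-9)
        assert res.retained == ("x", "y")

    def test_constant_column_excluded_with_reason(self, rng):
        res = correlation_screen(cov_table({"flat": np.ones(20), "x": rng.standard_normal(20)}))
        assert res.retained == ("x",)
        assert res.excluded[0].reason == "constant"

    def test_single_covariate_rejected(self, rng):
        with pytest.raises(PanelError):
            correlation_screen(cov_table({"x": rng.standard_normal(10)}))


class TestPanelIO:
    def test_csv_round_trip(self, tmp_path):
        panel = PanelData(("A", "B"), np.array([[10.0, 12], [8, 9]]), np.array([[20.0, 20], [15, 15]]))
        panel.write_csv(tmp_path / "panel.csv")
        back = PanelData.read_csv(tmp_path / "panel.csv", area_ids=("A", "B"))
        assert np.array_equal(panel.y, back.y)
        assert np.array_equal(panel.n, back.n)

    def test_covariate_round_trip(self, tmp_path, rng):
        cov = cov_table({"a": rng.standard_normal((4, 3))[:, 0], "b": rng.standard_normal(4)}, n_periods=2)
        cov.write_csv(tmp_path / "cov.csv")
        back = CovariateTable.read_csv(tmp_path / "cov.csv", area_ids=cov.area_ids)
        assert back.names == cov.names
        assert np.allclose(back.values, cov.values)

    def test_invalid_counts_rejected(self):
        with pytest.raises(PanelError):
            PanelData(("A",), np.array([[30.0]]), np.array([[20.0]]))
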