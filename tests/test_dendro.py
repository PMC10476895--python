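"""Ring-width I/O, detrending, chronology building, moving correlations."""

import io

import numpy as np
import pytest
from scipy import stats

from cambiomatch.dendro import (
    Chronology,
    IndexedSeries,
    RingWidthSeries,
    build_chronology,
    detrend_series,
    moving_correlation,
    read_ringwidth_csv,
    read_rwl,
    tukey_biweight_mean,
    write_rwl,
)
from cambiomatch.errors import AlignmentError, ContractError, FormatError


RWL_FIXTURE = """\
TREE01A 1971   100   110   120   130   140   150   160   170   180
TREE01A 1980   190   200   999
TREE02B 1975    50    60    70    80    90
TREE02B 1980   100   110   120   130   140   150   999
"""


class TestRwlIO:
    def test_fixture_parses_two_series(self):
        series = read_rwl(io.StringIO(RWL_FIXTURE))
        by_id = {s.series_id: s for s in series}
        assert set(by_id) == {"TREE01A", "TREE02B"}
        assert len(by_id["TREE01A"].years) == 11
        assert by_id["TREE01A"].years[0] == 1971
        assert by_id["TREE01A"].widths[0] == pytest.approx(1.00)
        assert len(by_id["TREE02B"].years) == 11

    def test_round_trip_identity(self, tmp_path, rng):
        series = [
            RingWidthSeries(
                "S1", np.arange(1950, 2000),
                np.round(rng.uniform(0.2, 3.0, 50), 3),
            ),
            RingWidthSeries(
                "S2", np.arange(1963, 2001),
                np.round(rng.uniform(0.2, 3.0, 38), 3),
            ),
        ]
        path = tmp_path / "out.rwl"
        write_rwl(series, path, precision=0.001)
        back = read_rwl(path)
        for orig, new in zip(series, back):
            assert orig.series_id == new.series_id
            np.testing.assert_array_equal(orig.years, new.years)
            np.testing.assert_allclose(orig.widths, new.widths, atol=5e-4)

    def test_marker_value_not_confused_with_data(self, tmp_path):
        # 0.999 mm encodes as 999 in the 0.001 dialect; must not truncate
        series = [RingWidthSeries("S1", np.arange(2000, 2010),
                                  np.full(10, 0.999))]
        path = tmp_path / "out.rwl"
        write_rwl(series, path, precision=0.001)
        (back,) = read_rwl(path)
        assert len(back.years) == 10
        np.testing.assert_allclose(back.widths, 0.999)

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(FormatError, match="line 2"):
            read_rwl(io.StringIO("GOOD    1990   100   999\nBAD     abc   def\n"))

    def test_csv_long_format(self):
        rows = ["series_id,year,width_mm"] + [
            f"X,{1970 + i},{1.0 + 0.01 * i}" for i in range(30)
        ]
        (s,) = read_ringwidth_csv(io.StringIO("\n".join(rows)))
        assert len(s.years) == 30
        assert s.widths[-1] == pytest.approx(1.29)


class TestDetrend:
    def test_constant_series_all_methods_give_unity(self):
        s = RingWidthSeries("c", np.arange(1960, 2000), np.full(40, 1.3))
        for method in ("spline", "negexp", "mean"):
            det = detrend_series(s, method=method)
            np.testing.assert_allclose(det.index, 1.0, atol=1e-6)

    def test_negexp_self_consistent_on_exact_curve(self):
        t = np.arange(60, dtype=float)
        widths = 1.5 * np.exp(-0.05 * t) + 0.4
        s = RingWidthSeries("e", 1940 + t.astype(int), widths)
        det = detrend_series(s, method="negexp", rescale=False)
        np.testing.assert_allclose(det.index, 1.0, atol=1e-4)

    def test_mean_detrending_preserves_trend(self):
        years = np.arange(1970, 2000)
        widths = np.linspace(2.0, 1.0, 30)
        s = RingWidthSeries("m", years, widths)
        det = detrend_series(s, method="mean")
        slope_w = np.polyfit(years, widths / widths.mean(), 1)[0]
        slope_i = np.polyfit(years, det.index, 1)[0]
        assert slope_i == pytest.approx(slope_w, rel=1e-9)

    def test_index_mean_is_one(self, rng):
        s = RingWidthSeries(
            "r", np.arange(1950, 2010),
            np.exp(rng.normal(0, 0.3, 60)) * np.linspace(2, 1, 60),
        )
        for method in ("spline", "mean", "negexp"):
            det = detrend_series(s, method=method)
            assert det.index.mean() == pytest.approx(1.0, abs=1e-9)

    def test_spline_needs_ten_years(self):
        s = RingWidthSeries("s", np.arange(2000, 2008), np.full(8, 1.0))
        with pytest.raises(ContractError):
            detrend_series(s, method="spline")

    def test_spline_removes_slow_trend(self, rng):
        years = np.arange(1930, 2010)
        trend = 2.5 * np.exp(-0.02 * np.arange(80)) + 0.5
        noise = np.exp(rng.normal(0, 0.15, 80))
        s = RingWidthSeries("t", years, trend * noise)
        det = detrend_series(s, method="spline")
        # index should be uncorrelated with the long-term trend direction
        slope = np.polyfit(years, det.index, 1)[0]
        assert abs(slope) < 0.003


class TestChronology:
    def test_duplicated_series_equals_series(self):
        years = np.arange(1980, 2000)
        idx = np.linspace(0.8, 1.2, 20)
        items = [IndexedSeries("a", years, idx), IndexedSeries("b", years, idx)]
        chron = build_chronology(items)
        np.testing.assert_allclose(chron.index, idx)
        assert np.all(chron.sample_depth == 2)

    def test_hand_mean_of_two_series(self):
        years = np.array([2000, 2001])
        a = IndexedSeries("a", years, np.array([1.0, 1.2]))
        b = IndexedSeries("b", years, np.array([1.2, 1.0]))
        chron = build_chronology([a, b])
        np.testing.assert_allclose(chron.index, [1.1, 1.1])

    def test_robust_mean_shrinks_outlier(self):
        years = np.arange(2000, 2020)
        items = [IndexedSeries(f"s{i}", years, np.ones(20)) for i in range(10)]
        items.append(IndexedSeries("out", years, np.full(20, 3.0)))
        plain = build_chronology(items).index[0]
        robust = build_chronology(items, robust=True).index[0]
        assert abs(robust - 1.0) < abs(plain - 1.0)

    def test_disjoint_series_rejected(self):
        a = IndexedSeries("a", np.arange(1900, 1920), np.ones(20))
        b = IndexedSeries("b", np.arange(1950, 1970), np.ones(20))
        with pytest.raises(ContractError):
            build_chronology([a, b])

    def test_biweight_ignores_far_outlier(self):
        x = np.array([1.0, 1.01, 0.99, 1.02, 0.98, 5.0])
        assert tukey_biweight_mean(x) == pytest.approx(1.0, abs=0.02)


def _chron(years, index):
    return Chronology("site", "tree", np.asarray(years), np.asarray(index),
                      np.ones(len(years), dtype=int))


class TestMovingCorrelation:
    def test_identical_series_r_one_everywhere(self, rng):
        years = np.arange(1960, 2001)
        vals = rng.normal(0, 1, 41)
        res = moving_correlation(_chron(years, vals), years, vals, window=21)
        np.testing.assert_allclose(res.r_values, 1.0)

    def test_window_count_and_centers(self, rng):
        years = np.arange(1960, 2001)
        res = moving_correlation(
            _chron(years, rng.normal(size=41)), years,
            rng.normal(size=41), window=21,
        )
        assert len(res.r_values) == 21
        assert res.center_years[0] == 1970
        assert res.center_years[-1] == 1990

    def test_matches_per_window_pearson_oracle(self, rng):
        years = np.arange(1950, 2000)
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        res = moving_correlation(_chron(years, a), years, b, window=15)
        for i in range(len(res.r_values)):
            r, p = stats.pearsonr(a[i : i + 15], b[i : i + 15])
            assert res.r_values[i] == pytest.approx(r, rel=1e-12)
            assert res.p_values[i] == pytest.approx(p, rel=1e-9)

    def test_coupling_breakdown_detected(self, rng):
        years = np.arange(1950, 2000)
        driver = rng.normal(size=50)
        response = driver.copy()
        response[25:] = rng.normal(size=25)  # decoupled second half
        res = moving_correlation(_chron(years, response), years, driver,
                                 window=15)
        assert res.r_values[0] > res.r_values[-1]

    def test_misaligned_years_rejected(self, rng):
        years = np.arange(1960, 2001)
        with pytest.raises(AlignmentError):
            moving_correlation(
                _chron(years, rng.normal(size=41)),
                years + 100, rng.normal(size=41),
            )
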