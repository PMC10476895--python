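"""Heat-unit forcing, chilling counting and the heat-vs-chilling LMM."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from hypothesis import given, settings, strategies as st

from cambiomatch.errors import ContractError, CoverageError, UndefinedRatioError
from cambiomatch.forcing_chilling import (
    ChillingWindow,
    DEFAULT_WINDOWS,
    PhenologyRecord,
    build_cf_table,
    cf_frame,
    chilling_days,
    daily_heat_unit,
    fit_heat_chilling_lmm,
    heat_sum,
    slope_ratio,
)

from conftest import climate_from_fn, constant_climate


class TestDailyHeatUnit:
    def test_midpoint_is_half_asymptote(self):
        assert daily_heat_unit(18.4) == pytest.approx(14.2)

    def test_saturates_at_asymptote(self):
        assert round(daily_heat_unit(100.0), 1) == 28.4

    def test_value_at_10_degrees(self):
        # direct evaluation: 28.4 / (1 + e^{0.185 * 8.4})
        assert daily_heat_unit(10.0) == pytest.approx(
            28.4 / (1 + np.exp(1.554)), rel=1e-12
        )

    def test_strictly_monotone_and_bounded(self):
        t = np.linspace(-40, 60, 2001)
        d = daily_heat_unit(t)
        assert np.all(np.diff(d) > 0)
        assert d.min() > 0 and d.max() < 28.4


class TestHeatSum:
    def test_below_threshold_accumulates_nothing(self):
        s = constant_climate(-5.0, 2000, 2000)
        assert heat_sum(s, 2000, 120) == 0.0

    def test_constant_midpoint_accumulates_linearly(self):
        s = constant_climate(18.4, 2000, 2000)
        assert heat_sum(s, 2000, 10) == pytest.approx(142.0)

    def test_includes_end_day(self):
        s = constant_climate(18.4, 2000, 2000)
        assert heat_sum(s, 2000, 1) == pytest.approx(14.2)

    def test_matches_day_by_day_loop(self, rng):
        t = rng.normal(2.0, 8.0, 366)
        dates = pd.date_range("2000-01-01", "2000-12-31", freq="D")
        from cambiomatch.climate import DailyClimateSeries

        s = DailyClimateSeries("x", dates, t)
        expected = sum(daily_heat_unit(v) for v in t[:200] if v > 0)
        assert heat_sum(s, 2000, 200) == pytest.approx(expected)

    def test_monotone_in_end_doy(self, rng):
        t = rng.normal(0.0, 10.0, 365)
        from cambiomatch.climate import DailyClimateSeries

        s = DailyClimateSeries(
            "x", pd.date_range("2001-01-01", "2001-12-31", freq="D"), t
        )
        sums = [heat_sum(s, 2001, d) for d in range(1, 366)]
        assert np.all(np.diff(sums) >= 0)


class TestChillingDays:
    def test_every_autumn_day_qualifies(self):
        s = constant_climate(-2.0, 1999, 2000)
        assert chilling_days(s, 2000, ChillingWindow(-5, 0)) == 122

    def test_no_day_qualifies(self):
        s = constant_climate(3.0, 1999, 2000)
        assert chilling_days(s, 2000, ChillingWindow(-5, 0)) == 0

    def test_alternating_days(self):
        def fn(dates):
            return np.where(np.arange(len(dates)) % 2 == 0, -2.0, 2.0)

        # Sep 1 1999 is day index 243 (odd parity shifts per start); build
        # the series so that exactly every second autumn day is -2
        s = climate_from_fn(fn, 1999, 2000)
        count = chilling_days(s, 2000, ChillingWindow(-5, 0))
        assert count == 61

    def test_bounds_are_half_open(self):
        s_low = constant_climate(-5.0, 1999, 2000)
        s_high = constant_climate(0.0, 1999, 2000)
        assert chilling_days(s_low, 2000, ChillingWindow(-5, 0)) == 122
        assert chilling_days(s_high, 2000, ChillingWindow(-5, 0)) == 0

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.normal(-2, 4, 731)
        from cambiomatch.climate import DailyClimateSeries

        s = DailyClimateSeries(
            "x", pd.date_range("1999-01-01", "2000-12-31", freq="D"), t
        )
        win = ChillingWindow(-5, 0)
        brute = sum(
            1
            for d, v in zip(s.dates, s.tmean)
            if d.year == 1999 and d.month >= 9 and win.lower <= v < win.upper
        )
        assert chilling_days(s, 2000, win) == brute


class TestBuildCfTable:
    def test_single_record_constant_climate(self):
        s = constant_climate(18.4, 1999, 2000, site_id="a")
        rec = PhenologyRecord("a", "sp", "tree", 2000, 5)
        (out,) = build_cf_table([rec], {"a": s})
        assert out.heat_units == pytest.approx(71.0)
        assert out.chill_days == 0

    def test_empty_phenology_gives_empty_table(self):
        assert build_cf_table([], {}) == []

    def test_missing_previous_autumn_is_coverage_error(self):
        s = constant_climate(5.0, 2000, 2000, site_id="a")
        rec = PhenologyRecord("a", "sp", "tree", 2000, 100)
        with pytest.raises(CoverageError, match="2000"):
            build_cf_table([rec], {"a": s})

    def test_heat_units_nondecreasing_in_onset(self, rng):
        s = climate_from_fn(
            lambda d: rng.normal(5, 8, len(d)), 1999, 2000, site_id="a"
        )
        recs = [
            PhenologyRecord("a", "sp", "tree", 2000, doy)
            for doy in range(50, 250, 10)
        ]
        table = build_cf_table(recs, {"a": s})
        hu = [r.heat_units for r in table]
        assert np.all(np.diff(hu) >= 0)


def _synthetic_lmm_frame(rng, n_sites=1, n_species=1, noise=0.01,
                         beta=(150.0, -2.0, -60.0, 1.3)):
    """heat_units from known coefficients (tree-reference coding)."""
    rows = []
    b0, b_ch, b_lf, b_int = beta
    for site in range(n_sites):
        for sp in range(n_species):
            for form, lf in (("tree", 0.0), ("shrub", 1.0)):
                for _ in range(30):
                    chill = float(rng.integers(20, 90))
                    hu = (
                        b0 + b_ch * chill + b_lf * lf + b_int * chill * lf
                        + rng.normal(0, noise)
                    )
                    rows.append(
                        {
                            "site_id": f"s{site}",
                            "species": f"{form}{sp}",
                            "life_form": form,
                            "year": 2000,
                            "onset_doy": 150,
                            "chill_days": chill,
                            "heat_units": hu,
                            "spring_t": 0.0,
                            "winter_t": -5.0,
                        }
                    )
    return pd.DataFrame(rows)


class TestHeatChillingLmm:
    def test_single_group_reduces_to_ols(self, rng):
        df = _synthetic_lmm_frame(rng, noise=0.5)
        df["species"] = "sp"  # single site, single species: no random structure
        res = fit_heat_chilling_lmm(df, reference="tree")
        ols = smf.ols(
            "heat_units ~ chill_days * lf",
            data=df.assign(lf=(df.life_form != "tree").astype(float)),
        ).fit()
        np.testing.assert_allclose(
            res.fixed_effects["estimate"].to_numpy(),
            ols.params.to_numpy(),
            rtol=1e-6,
        )
        assert res.aic == pytest.approx(ols.aic, rel=1e-9)

    def test_recovers_known_coefficients(self, rng):
        df = _synthetic_lmm_frame(rng, n_sites=4, n_species=2, noise=3.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_heat_chilling_lmm(df, reference="tree")
        est = res.fixed_effects["estimate"]
        se = res.fixed_effects["se"]
        truth = {"Intercept": 150.0, "Chilling": -2.0, "Life form": -60.0,
                 "Chilling x life form": 1.3}
        for term, value in truth.items():
            assert abs(est[term] - value) < 3 * se[term] + 1e-9

    def test_table_has_four_canonical_rows(self, rng):
        df = _synthetic_lmm_frame(rng)
        res = fit_heat_chilling_lmm(df)
        assert list(res.fixed_effects.index) == [
            "Intercept", "Chilling", "Life form", "Chilling x life form",
        ]

    def test_single_life_form_is_contract_error(self, rng):
        df = _synthetic_lmm_frame(rng)
        with pytest.raises(ContractError):
            fit_heat_chilling_lmm(df[df.life_form == "tree"])

    def test_reference_codings_agree_on_slopes(self, rng):
        df = _synthetic_lmm_frame(rng, noise=0.5)
        a = fit_heat_chilling_lmm(df, reference="tree")
        b = fit_heat_chilling_lmm(df, reference="shrub")
        assert slope_ratio(a) == pytest.approx(slope_ratio(b), rel=1e-6)
        # interaction flips sign between codings
        assert a.coef("Chilling x life form") == pytest.approx(
            -b.coef("Chilling x life form"), rel=1e-6
        )


class TestSlopeRatio:
    def _result(self, chilling, interaction, reference="shrub"):
        from cambiomatch.forcing_chilling import LmmResult

        fe = pd.DataFrame(
            {
                "estimate": [100.0, chilling, -50.0, interaction],
                "se": [1.0] * 4,
                "t": [1.0] * 4,
            },
            index=["Intercept", "Chilling", "Life form", "Chilling x life form"],
        )
        return LmmResult(fixed_effects=fe, random_effect_variances={},
                         aic=0.0, n_obs=10, reference=reference)

    def test_published_style_coefficients(self):
        # shrub-reference slopes: shrub -1.96, tree -1.96 + 1.28 = -0.68
        res = self._result(-1.96, 1.28)
        assert slope_ratio(res) == pytest.approx(-1.96 / -0.68, rel=1e-12)

    def test_equal_slopes_give_unity(self):
        assert slope_ratio(self._result(-2.0, 0.0)) == pytest.approx(1.0)

    def test_zero_tree_slope_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            slope_ratio(self._result(-2.0, 2.0))

    def test_default_candidate_set_has_four_windows(self):
        assert len(DEFAULT_WINDOWS) == 4
        assert ChillingWindow(-5.0, 0.0) in DEFAULT_WINDOWS
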