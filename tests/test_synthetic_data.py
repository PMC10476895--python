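"""Synthetic study generator: determinism, construction rules, recovery."""

import json

import numpy as np
import pytest

from cambiomatch.errors import ConfigError
from cambiomatch.forcing_chilling import chilling_days, heat_cumsum
from cambiomatch.synthetic_data import (
    SynthClimateConfig,
    SynthGrowthConfig,
    SynthPhenoConfig,
    generate_climate,
    generate_phenology,
    generate_ring_widths,
    make_study,
    parse_series_id,
    series_id_for,
    write_study,
)


class TestGenerateClimate:
    def test_same_seed_identical(self):
        cfg = SynthClimateConfig(seed=9)
        a = generate_climate(cfg)
        b = generate_climate(cfg)
        np.testing.assert_array_equal(a.tmean, b.tmean)
        np.testing.assert_array_equal(a.prcp, b.prcp)

    def test_deterministic_cycle_matches_closed_form(self):
        cfg = SynthClimateConfig(
            years=(2000, 2000), daily_noise_sd=0.0, annual_anomaly_sd=0.0,
            spring_trend=0.0, winter_trend=0.0, seed=1,
        )
        clim = generate_climate(cfg)
        doy = np.arange(1, 367)  # 2000 is a leap year
        phase = 2 * np.pi * (doy - cfg.peak_doy) / 365.0
        expected = (
            cfg.mean_annual_t
            + cfg.seasonal_amplitude * np.cos(phase)
            + cfg.seasonal_asymmetry * np.sin(2 * phase)
        )
        np.testing.assert_allclose(clim.tmean, expected, atol=1e-12)

    def test_spring_trend_recovered_by_regression(self):
        cfg = SynthClimateConfig(
            years=(1970, 2019), spring_trend=0.5, winter_trend=0.0,
            daily_noise_sd=0.3, annual_anomaly_sd=0.0, seed=3,
        )
        clim = generate_climate(cfg)
        from cambiomatch.climate import seasonal_means

        years = np.arange(1970, 2020)
        spring = np.array([m.spring for m in seasonal_means(clim, years[1:])])
        slope, _ = np.polyfit(years[1:], spring, 1)
        # 0.5 degC/decade = 0.05 degC/yr
        assert slope == pytest.approx(0.05, abs=0.01)

    def test_invalid_ar1_rejected(self):
        with pytest.raises(ConfigError):
            SynthClimateConfig(ar1_coefficient=1.2)


class TestGeneratePhenology:
    def test_onsets_match_day_loop_oracle(self):
        ccfg = SynthClimateConfig(years=(1995, 2005), seed=4)
        clim = generate_climate(ccfg, site_id="site01")
        pcfg = SynthPhenoConfig(
            onset_noise_sd=0.0, n_sites=1, n_species_per_form=1,
            site_sd=0.0, species_sd=0.0, seed=4,
        )
        records, truth = generate_phenology({"site01": clim}, pcfg)
        for rec in records:
            intercept = truth["hu_intercepts"][rec.life_form]
            slope = truth["hu_chill_slopes"][rec.life_form]
            chill = chilling_days(clim, rec.year, pcfg.chilling_window)
            hu_star = intercept + slope * chill
            cum = heat_cumsum(clim, rec.year)
            oracle = next(
                (d + 1 for d in range(len(cum)) if cum[d] >= hu_star), None
            )
            assert rec.onset_doy == oracle

    def test_warm_winter_raises_shrub_requirement_more(self):
        pcfg = SynthPhenoConfig()
        chill_cold, chill_warm = 70, 40  # warmer autumn, fewer chilling days
        rise_shrub = pcfg.hu_chill_slope_shrub * (chill_warm - chill_cold)
        rise_tree = pcfg.hu_chill_slope_tree * (chill_warm - chill_cold)
        assert rise_shrub > rise_tree > 0

    def test_more_chilling_weakly_earlier_onset(self):
        # identical growth-year climate, colder previous autumn -> more
        # chilling days -> lower requirement -> weakly earlier onset
        import pandas as pd

        from cambiomatch.climate import DailyClimateSeries

        ccfg = SynthClimateConfig(years=(1999, 2000), daily_noise_sd=0.0,
                                  annual_anomaly_sd=0.0, spring_trend=0.0,
                                  winter_trend=0.0, seed=0)
        base = generate_climate(ccfg, site_id="site01")
        chilled = base.tmean.copy()
        autumn = (base.dates.year == 1999) & (base.dates.month >= 9)
        chilled[autumn & (base.tmean > 0)] = -2.0  # push autumn into the window
        colder = DailyClimateSeries("site01", base.dates, chilled,
                                    latitude=base.latitude)
        pcfg = SynthPhenoConfig(onset_noise_sd=0.0, n_sites=1,
                                n_species_per_form=1, site_sd=0.0,
                                species_sd=0.0, seed=0)
        warm_recs, _ = generate_phenology({"site01": base}, pcfg)
        cold_recs, _ = generate_phenology({"site01": colder}, pcfg)
        warm = {(r.life_form): r.onset_doy for r in warm_recs}
        cold = {(r.life_form): r.onset_doy for r in cold_recs}
        assert chilling_days(colder, 2000, pcfg.chilling_window) > \
            chilling_days(base, 2000, pcfg.chilling_window)
        for form in warm:
            assert cold[form] <= warm[form]

    def test_default_slope_ratio_is_3_2(self):
        assert SynthPhenoConfig().slope_ratio == pytest.approx(3.2)


class TestGenerateRingWidths:
    def test_zero_noise_perfectly_anticorrelated(self, default_study):
        cfg = SynthGrowthConfig(width_noise_sd=0.0, seed=2)
        series = generate_ring_widths(default_study.phenology, cfg)
        onset_map = {
            (series_id_for(r.site_id, r.species), r.year): r.onset_doy
            for r in default_study.phenology
        }
        s = series[0]
        onsets = [onset_map[(s.series_id, int(y))] for y in s.years]
        r = np.corrcoef(onsets, s.widths)[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_slope_recovered_within_three_se(self, default_study):
        cfg = SynthGrowthConfig(seed=3)
        series = generate_ring_widths(default_study.phenology, cfg)
        onset_map = {
            (series_id_for(r.site_id, r.species), r.year): r.onset_doy
            for r in default_study.phenology
        }
        onsets, widths = [], []
        for s in series:
            for y, w in zip(s.years, s.widths):
                onsets.append(onset_map[(s.series_id, int(y))])
                widths.append(w)
        import statsmodels.api as sm

        x = sm.add_constant(np.array(onsets, float))
        fit = sm.OLS(np.array(widths), x).fit()
        assert abs(fit.params[1] - cfg.width_onset_slope) < 3 * fit.bse[1]

    def test_floor_keeps_widths_positive(self):
        from cambiomatch.forcing_chilling import PhenologyRecord

        recs = [
            PhenologyRecord("site01", "tree_sp1", "tree", 2000 + i, 360)
            for i in range(5)
        ]
        cfg = SynthGrowthConfig(width_intercept=0.5, width_noise_sd=0.0, seed=1)
        (s,) = generate_ring_widths(recs, cfg)
        assert np.all(s.widths >= cfg.floor)


class TestMakeStudy:
    def test_record_count_arithmetic(self):
        ccfg = SynthClimateConfig(years=(1990, 2019))
        pcfg = SynthPhenoConfig(n_sites=2, n_species_per_form=1)
        bundle = make_study(climate_config=ccfg, pheno_config=pcfg, seed=5)
        # 2 sites x 2 life forms x 1 species x 29 usable years, less censored
        expected = 2 * 2 * 1 * 29 - bundle.truth["censored"]
        assert len(bundle.phenology) == expected

    def test_same_master_seed_byte_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            bundle = make_study(
                pheno_config=SynthPhenoConfig(n_sites=2),
                climate_config=SynthClimateConfig(years=(2000, 2010)),
                seed=7,
            )
            write_study(bundle, tmp_path / sub)
        for name in ("inputs/phenology.csv", "inputs/ring_widths.rwl",
                     "inputs/climate_site01.csv", "truth/truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_truth_kept_out_of_inputs(self, tmp_path):
        bundle = make_study(
            pheno_config=SynthPhenoConfig(n_sites=2),
            climate_config=SynthClimateConfig(years=(2000, 2010)),
            seed=7,
            out_dir=tmp_path,
        )
        inputs = {p.name for p in (tmp_path / "inputs").iterdir()}
        assert "truth.json" not in inputs
        truth = json.loads((tmp_path / "truth" / "truth.json").read_text())
        assert truth["slope_ratio"] == pytest.approx(3.2)

    def test_series_id_round_trip(self):
        sid = series_id_for("site07", "shrub_sp2")
        assert len(sid) <= 8
        assert parse_series_id(sid) == ("site07", "shrub_sp2", "shrub")
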