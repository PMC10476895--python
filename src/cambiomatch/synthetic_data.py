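"""Synthetic treeline study generator.

Produces daily climate, cambial-onset records and ring-width series with
the statistical structure the analysis modules assume, so the whole
pipeline — chilling-window selection, the heat-vs-chilling mixed model,
the divergent onset-vs-spring-temperature responses of trees and shrubs,
and the onset-ring-width coupling — can be exercised and validated as a
recovery of known generating parameters.

Climate is a sinusoidal seasonal cycle with its annual peak in early
August (the thermal lag of high-elevation monsoon climates, which makes
autumn milder than spring at equal distance from the peak), plus daily
AR(1) weather noise, a yearly AR(1) temperature anomaly shared by all
days of a year (slow interannual variability that couples the previous
autumn to the following spring), and month-specific linear warming
trends: spring months warm at ``spring_trend`` and the cold-season
months (September-February) at ``winter_trend`` deg C per decade,
emulating the faster cold-season warming observed at high elevations.

Onset dates follow a chilling-dependent heat-requirement rule: the
requirement HU* = intercept + slope x chilling-days declines with
chilling, with the shrub slope 3.2 times the tree slope by default, and
onset is the first day the accumulated heat units reach HU* (plus
observation noise in days). Ring-width indices decline linearly with
onset day. The generating parameters are returned in a separate truth
table that the analysis stages never read.
"""

from __future__ import annotations

import calendar
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .climate import DailyClimateSeries
from .dendro import RingWidthSeries
from .errors import ConfigError
from .forcing_chilling import (
    ChillingWindow,
    PhenologyRecord,
    chilling_days,
    heat_cumsum,
)

SPRING_TREND_MONTHS = (3, 4, 5)
COLD_TREND_MONTHS = (9, 10, 11, 12, 1, 2)

_FORM_CODE = {"tree": "t", "shrub": "h"}
_CODE_FORM = {v: k for k, v in _FORM_CODE.items()}


def series_id_for(site_id: str, species: str) -> str:
    """Compact (<= 8 char) Tucson-compatible series id, e.g. s01t1."""
    site_num = "".join(ch for ch in site_id if ch.isdigit()) or "0"
    form, _, num = species.partition("_sp")
    return f"s{int(site_num):02d}{_FORM_CODE[form]}{num or '1'}"


def parse_series_id(series_id: str) -> tuple[str, str, str]:
    """Invert :func:`series_id_for` -> (site_id, species, life_form)."""
    if not (series_id.startswith("s") and len(series_id) >= 4):
        raise ConfigError(f"not a synthetic series id: {series_id!r}")
    site = f"site{int(series_id[1:3]):02d}"
    form = _CODE_FORM[series_id[3]]
    species = f"{form}_sp{series_id[4:]}"
    return site, species, form


@dataclass
class SynthClimateConfig:
    """Daily-temperature generator settings (deg C, mm, decimal degrees).

    Defaults emulate a high-elevation monsoon treeline: annual mean just
    below freezing, moderate seasonal amplitude with an early-August
    thermal peak, persistent daily weather noise, slow interannual
    anomalies, and asymmetric seasonal warming trends.
    """

    years: tuple[int, int] = (1980, 2019)
    latitude: float = 29.6
    mean_annual_t: float = -0.75
    seasonal_amplitude: float = 5.5
    seasonal_asymmetry: float = -1.9
    peak_doy: int = 225
    ar1_coefficient: float = 0.5
    daily_noise_sd: float = 1.4
    annual_anomaly_sd: float = 1.1
    annual_anomaly_ar1: float = 0.8
    spring_trend: float = 0.35  # deg C per decade, months 3-5
    winter_trend: float = 0.7   # deg C per decade, months 9-2
    precip_mean: float = 2.5    # mm/day
    seed: int = 0

    def __post_init__(self):
        if abs(self.ar1_coefficient) >= 1 or abs(self.annual_anomaly_ar1) >= 1:
            raise ConfigError("AR(1) coefficients must have |rho| < 1")
        if self.daily_noise_sd < 0 or self.annual_anomaly_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.years[0] > self.years[1]:
            raise ConfigError("years range reversed")


@dataclass
class SynthPhenoConfig:
    """Chilling-dependent heat-requirement rule for onset generation.

    Intercepts and slopes are in heat units; the default shrub:tree slope
    ratio is 3.2, matching the stronger chilling sensitivity of shrubs.
    Site and species random offsets (heat units) create the grouping
    structure the mixed model estimates.
    """

    hu_intercept_tree: float = 94.0
    hu_intercept_shrub: float = 186.5
    hu_chill_slope_tree: float = -0.6125
    hu_chill_slope_shrub: float = -1.96
    onset_noise_sd: float = 2.5
    chilling_window: ChillingWindow = field(
        default_factory=lambda: ChillingWindow(-5.0, 0.0)
    )
    n_sites: int = 8
    n_species_per_form: int = 2
    site_sd: float = 6.0
    species_sd: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.hu_chill_slope_tree > 0 or self.hu_chill_slope_shrub > 0:
            raise ConfigError("chilling slopes must be <= 0 (chilling lowers HU*)")

    @property
    def slope_ratio(self) -> float:
        return self.hu_chill_slope_shrub / self.hu_chill_slope_tree


@dataclass
class SynthGrowthConfig:
    """Linear onset-to-ring-width rule (earlier onset, wider ring)."""

    width_intercept: float = 2.2
    width_onset_slope: float = -0.008  # index units per day, negative
    width_noise_sd: float = 0.12
    floor: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.width_onset_slope >= 0:
            raise ConfigError("width_onset_slope must be negative")


@dataclass
class StudyBundle:
    """Complete synthetic dataset plus the hidden generating truth."""

    climates: dict[str, DailyClimateSeries]
    phenology: list[PhenologyRecord]
    ring_widths: list[RingWidthSeries]
    truth: dict


def _doy_array(year: int) -> np.ndarray:
    n = 366 if calendar.isleap(year) else 365
    return np.arange(1, n + 1)


def generate_climate(
    config: SynthClimateConfig,
    site_id: str = "synth",
    offset: float = 0.0,
) -> DailyClimateSeries:
    """Generate one site's daily temperature and precipitation series.

    ``offset`` shifts the whole series (an elevation ladder across sites).
    Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.years
    n_years = y1 - y0 + 1

    # yearly AR(1) anomaly shared by all days of a calendar year
    anomalies = np.empty(n_years)
    rho_y = config.annual_anomaly_ar1
    innov_sd = config.annual_anomaly_sd * np.sqrt(1 - rho_y**2)
    state = rng.normal(0.0, config.annual_anomaly_sd)
    for i in range(n_years):
        anomalies[i] = state
        state = rho_y * state + rng.normal(0.0, innov_sd)

    pieces_t, pieces_p, months_all = [], [], []
    for i, year in enumerate(range(y0, y1 + 1)):
        doy = _doy_array(year)
        phase = 2 * np.pi * (doy - config.peak_doy) / 365.0
        # second harmonic skews the cycle: steep spring warming, slow mild
        # autumn cooling (negative values), as in monsoon mountain climates
        seasonal = (
            config.mean_annual_t
            + config.seasonal_amplitude * np.cos(phase)
            + config.seasonal_asymmetry * np.sin(2 * phase)
        )
        dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        months_all.append(dates.month.to_numpy())
        decades = (year - y0) / 10.0
        trend = np.zeros(len(doy))
        trend[np.isin(dates.month, SPRING_TREND_MONTHS)] = config.spring_trend * decades
        trend[np.isin(dates.month, COLD_TREND_MONTHS)] = config.winter_trend * decades
        pieces_t.append(seasonal + trend + anomalies[i] + offset)
        pieces_p.append(rng.exponential(config.precip_mean, size=len(doy)))

    tmean = np.concatenate(pieces_t)
    # daily AR(1) weather noise across the whole span
    rho = config.ar1_coefficient
    eps = rng.normal(0.0, config.daily_noise_sd * np.sqrt(1 - rho**2), size=len(tmean))
    noise = np.empty(len(tmean))
    prev = rng.normal(0.0, config.daily_noise_sd)
    for i in range(len(tmean)):
        prev = rho * prev + eps[i]
        noise[i] = prev
    tmean = tmean + noise

    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    return DailyClimateSeries(
        site_id=site_id,
        dates=dates,
        tmean=tmean,
        prcp=np.concatenate(pieces_p),
        latitude=config.latitude,
    )


def generate_phenology(
    climates: Mapping[str, DailyClimateSeries],
    config: SynthPhenoConfig,
) -> tuple[list[PhenologyRecord], dict]:
    """Generate onset records from the chilling-dependent heat rule.

    For each (site, species, year): count chilling days in the previous
    autumn, set the requirement HU* from the life form's line plus site
    and species offsets, and take onset as the first day the cumulative
    heat sum reaches HU*, plus Gaussian day noise clipped to [1, 366].
    Years whose requirement is never met are censored (dropped) and
    counted in the truth table.
    """
    rng = np.random.default_rng(config.seed)
    forms = {
        "tree": (config.hu_intercept_tree, config.hu_chill_slope_tree),
        "shrub": (config.hu_intercept_shrub, config.hu_chill_slope_shrub),
    }
    site_ids = sorted(climates)
    site_offsets = {s: float(rng.normal(0.0, config.site_sd)) for s in site_ids}
    species_offsets: dict[str, float] = {}
    records: list[PhenologyRecord] = []
    censored = 0

    for site in site_ids:
        series = climates[site]
        first_year = int(series.start.year) + 1  # need previous autumn
        last_year = int(series.end.year)
        for form in ("tree", "shrub"):
            intercept, slope = forms[form]
            for k in range(config.n_species_per_form):
                species = f"{form}_sp{k + 1}"
                if species not in species_offsets:
                    species_offsets[species] = float(rng.normal(0.0, config.species_sd))
                for year in range(first_year, last_year + 1):
                    chill = chilling_days(series, year, config.chilling_window)
                    hu_star = (
                        intercept
                        + slope * chill
                        + site_offsets[site]
                        + species_offsets[species]
                    )
                    cum = heat_cumsum(series, year)
                    hit = np.searchsorted(cum, max(hu_star, 0.0))
                    if hit >= len(cum):
                        censored += 1
                        continue
                    onset = int(
                        np.clip(
                            round(hit + 1 + rng.normal(0.0, config.onset_noise_sd)),
                            1,
                            len(cum),
                        )
                    )
                    records.append(
                        PhenologyRecord(
                            site_id=site,
                            species=species,
                            life_form=form,
                            year=year,
                            onset_doy=onset,
                        )
                    )

    truth = {
        "hu_intercepts": {
            "tree": config.hu_intercept_tree,
            "shrub": config.hu_intercept_shrub,
        },
        "hu_chill_slopes": {
            "tree": config.hu_chill_slope_tree,
            "shrub": config.hu_chill_slope_shrub,
        },
        "slope_ratio": config.slope_ratio,
        "chilling_window": [config.chilling_window.lower, config.chilling_window.upper],
        "onset_noise_sd": config.onset_noise_sd,
        "site_offsets": site_offsets,
        "species_offsets": species_offsets,
        "censored": censored,
    }
    return records, truth


def generate_ring_widths(
    phenology: list[PhenologyRecord],
    config: SynthGrowthConfig,
) -> list[RingWidthSeries]:
    """Turn onset records into per-(site, species) ring-width series.

    index = intercept + slope * onset + noise, floored at a small positive
    value; years missing from a series (censored onsets) break it at the
    longest consecutive run so series stay contiguous.
    """
    if not phenology:
        raise ConfigError("no phenology records supplied")
    rng = np.random.default_rng(config.seed)
    df = pd.DataFrame(
        [
            {"site": r.site_id, "species": r.species, "year": r.year,
             "onset": r.onset_doy}
            for r in phenology
        ]
    )
    out = []
    for (site, species), grp in df.groupby(["site", "species"], sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(int)
        # keep the longest consecutive run
        breaks = np.flatnonzero(np.diff(years) != 1)
        segments = np.split(np.arange(len(years)), breaks + 1)
        seg = max(segments, key=len)
        years = years[seg]
        onsets = grp["onset"].to_numpy(float)[seg]
        widths = (
            config.width_intercept
            + config.width_onset_slope * onsets
            + rng.normal(0.0, config.width_noise_sd, size=len(onsets))
        )
        widths = np.maximum(widths, config.floor)
        out.append(
            RingWidthSeries(series_id=series_id_for(site, species),
                            years=years, widths=widths)
        )
    return out


def make_study(
    climate_config: SynthClimateConfig | None = None,
    pheno_config: SynthPhenoConfig | None = None,
    growth_config: SynthGrowthConfig | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> StudyBundle:
    """Generate the full multi-site, two-life-form study bundle.

    When ``seed`` is given it overrides the per-config seeds through a
    deterministic seed sequence, so one master seed reproduces the whole
    dataset byte-for-byte. With ``out_dir`` the standard input files are
    written under ``<out_dir>/inputs`` and the generating truth under the
    separate ``<out_dir>/truth`` directory, which no analysis stage reads.
    """
    from dataclasses import replace

    climate_config = climate_config or SynthClimateConfig()
    pheno_config = pheno_config or SynthPhenoConfig()
    growth_config = growth_config or SynthGrowthConfig()
    if seed is not None:
        children = np.random.SeedSequence(seed).spawn(3)
        sub = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in children]
        climate_config = replace(climate_config, seed=sub[0])
        pheno_config = replace(pheno_config, seed=sub[1])
        growth_config = replace(growth_config, seed=sub[2])

    n_sites = pheno_config.n_sites
    # elevation ladder: evenly spaced negative offsets, site seeds distinct
    climates = {}
    for i in range(n_sites):
        site_id = f"site{i + 1:02d}"
        site_cfg = SynthClimateConfig(**{**asdict(climate_config),
                                         "seed": climate_config.seed + i})
        climates[site_id] = generate_climate(
            site_cfg, site_id=site_id,
            offset=-0.8 * i / max(n_sites - 1, 1),
        )

    phenology, truth = generate_phenology(climates, pheno_config)
    ring_widths = generate_ring_widths(phenology, growth_config)
    truth["configs"] = {
        "climate": asdict(climate_config),
        "phenology": {
            **{k: v for k, v in asdict(pheno_config).items()
               if k != "chilling_window"},
            "chilling_window": [pheno_config.chilling_window.lower,
                                pheno_config.chilling_window.upper],
        },
        "growth": asdict(growth_config),
    }

    bundle = StudyBundle(
        climates=climates,
        phenology=phenology,
        ring_widths=ring_widths,
        truth=truth,
    )
    if out_dir is not None:
        write_study(bundle, out_dir)
    return bundle


def write_study(bundle: StudyBundle, out_dir: str | Path) -> dict[str, str]:
    """Write the bundle to the standard file formats the readers ingest."""
    from .dendro import write_rwl
    from .forcing_chilling import write_phenology_csv

    out_dir = Path(out_dir)
    inputs = out_dir / "inputs"
    truth_dir = out_dir / "truth"
    inputs.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)

    paths: dict[str, str] = {}
    for site_id, series in bundle.climates.items():
        p = inputs / f"climate_{site_id}.csv"
        series.to_csv(p)
        paths[f"climate_{site_id}"] = str(p)
    p = inputs / "phenology.csv"
    write_phenology_csv(bundle.phenology, p)
    paths["phenology"] = str(p)
    p = inputs / "ring_widths.rwl"
    write_rwl(bundle.ring_widths, p, precision=0.001)
    paths["ring_widths"] = str(p)
    p = truth_dir / "truth.json"
    with open(p, "w") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
    paths["truth"] = str(p)
    return paths
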