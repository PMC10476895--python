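"""Process-based daily growth simulator in the Vaganov-Shashkin tradition.

The simulator converts daily climate into a daily relative growth rate

    G(d) = L(d) * min(gT(d), gM(d)),

where ``gT`` and ``gM`` are piecewise-linear ramp responses to daily mean
temperature and volumetric soil moisture, and ``L`` is the astronomical
day length normalized to its annual maximum. Soil moisture follows a
leaky-bucket water balance; for humid treeline sites it is disabled by
default so growth is temperature- and insolation-limited only. The day of
cambial onset is read off the simulation as the first day on which the
temperature response is positive for a configurable number of consecutive
days; annual ring-width increments are the within-year sums of ``G`` and
are standardized to mean one before any comparison with observed
chronologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .climate import DailyClimateSeries
from .errors import ContractError, ParameterError

MAX_LATITUDE = 66.6


@dataclass(frozen=True)
class BucketParams:
    """Leaky-bucket soil hydrology constants.

    capacity_mm      maximum plant-available water storage
    runoff_frac      fraction of daily precipitation lost to runoff
    drainage_rate    fractional daily drainage loss of stored water
    et_coef          evapotranspiration per degree-day per unit relative
                     storage (mm / degC / day); zero when tmean <= 0
    """

    capacity_mm: float = 200.0
    runoff_frac: float = 0.3
    drainage_rate: float = 0.01
    et_coef: float = 0.1

    def __post_init__(self):
        if self.capacity_mm <= 0:
            raise ParameterError("bucket capacity must be positive")
        if not 0 <= self.runoff_frac < 1:
            raise ParameterError("runoff fraction must be in [0, 1)")
        if self.drainage_rate < 0 or self.et_coef < 0:
            raise ParameterError("drainage and ET coefficients must be >= 0")


@dataclass(frozen=True)
class VSParameters:
    """Growth-response parameter vector.

    Temperature thresholds ``t1 < t2 <= t3 < t4`` (deg C): growth begins
    above ``t1``, is optimal on ``[t2, t3]`` and ceases above ``t4``.
    Moisture thresholds ``m1..m4`` play the same role on volumetric soil
    moisture (v/v). ``onset_persistence`` is the number of consecutive
    days with a positive temperature response required to declare cambial
    onset.
    """

    t1: float = 4.0
    t2: float = 11.0
    t3: float = 20.0
    t4: float = 28.0
    m1: float = 0.02
    m2: float = 0.15
    m3: float = 0.60
    m4: float = 0.90
    bucket: BucketParams = field(default_factory=BucketParams)
    onset_persistence: int = 5
    moisture_enabled: bool = False
    combine: str = "min"  # or "product"

    def __post_init__(self):
        _check_ramp(self.t1, self.t2, self.t3, self.t4, "temperature")
        _check_ramp(self.m1, self.m2, self.m3, self.m4, "moisture")
        if self.onset_persistence < 1:
            raise ParameterError("onset_persistence must be >= 1")
        if self.combine not in ("min", "product"):
            raise ParameterError("combine must be 'min' or 'product'")

    def with_updates(self, **kwargs) -> "VSParameters":
        return replace(self, **kwargs)


@dataclass
class GrowthYear:
    """One simulated growth season."""

    year: int
    daily_rate: np.ndarray
    onset_doy: int | None
    annual_increment: float


@dataclass
class SimulatedChronology:
    """Standardized simulated ring-width indices with per-year onsets."""

    years: np.ndarray
    index: np.ndarray
    onsets: list[int | None]
    increments: np.ndarray


def _check_ramp(x1, x2, x3, x4, what: str) -> None:
    if not (x1 < x2 <= x3 < x4):
        raise ParameterError(
            f"{what} thresholds must satisfy x1 < x2 <= x3 < x4, "
            f"got ({x1}, {x2}, {x3}, {x4})"
        )


def ramp_response(x, x1: float, x2: float, x3: float, x4: float):
    """Trapezoidal partial growth rate: 0 outside (x1, x4), 1 on [x2, x3]."""
    _check_ramp(x1, x2, x3, x4, "ramp")
    x = np.asarray(x, dtype=float)
    up = (x - x1) / (x2 - x1)
    down = (x4 - x) / (x4 - x3)
    out = np.clip(np.minimum(up, down), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def daylength_hours(doy, latitude: float):
    """Astronomical day length (h) from solar declination and hour angle."""
    doy = np.asarray(doy, dtype=float)
    decl = np.deg2rad(-23.44 * np.cos(2 * np.pi * (doy + 10.0) / 365.0))
    lat = np.deg2rad(latitude)
    cos_h = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_h)


@lru_cache(maxsize=64)
def _daylength_factor_year(latitude: float, n_days: int) -> np.ndarray:
    doy = np.arange(1, n_days + 1)
    hours = daylength_hours(doy, latitude)
    return hours / hours.max()


def daylength_factor(doy, latitude: float, n_days: int = 365):
    """Day length normalized to its within-year maximum (thus in (0, 1]).

    Latitudes poleward of the polar circles are unsupported: day length
    there degenerates to polar day/night.
    """
    if abs(latitude) >= MAX_LATITUDE:
        raise ParameterError(f"latitude {latitude} outside supported range")
    factors = _daylength_factor_year(round(float(latitude), 4), n_days)
    idx = np.asarray(doy, dtype=int) - 1
    out = factors[idx]
    return float(out) if out.ndim == 0 else out


def soil_moisture_step(m_prev: float, prcp: float, tmean: float,
                       bucket: BucketParams) -> float:
    """One day of the leaky-bucket balance, in volumetric units (v/v).

    ``m_prev`` is relative storage W/capacity in [0, 1]. Infiltration adds
    precipitation net of runoff; losses are a temperature-index
    evapotranspiration (zero at or below 0 deg C) and linear drainage.
    """
    if prcp < 0:
        raise ParameterError("negative precipitation")
    if not 0 <= m_prev <= 1:
        raise ParameterError("soil moisture out of [0, 1]")
    w = m_prev * bucket.capacity_mm
    infiltration = prcp * (1.0 - bucket.runoff_frac)
    et = bucket.et_coef * max(tmean, 0.0) * m_prev if tmean > 0 else 0.0
    drainage = bucket.drainage_rate * w
    w_next = np.clip(w + infiltration - et - drainage, 0.0, bucket.capacity_mm)
    return float(w_next / bucket.capacity_mm)


def _find_onset(growing: np.ndarray, persistence: int) -> int | None:
    """First 1-based day index opening a run of ``persistence`` growing days."""
    if persistence == 1:
        hits = np.flatnonzero(growing)
        return int(hits[0]) + 1 if hits.size else None
    kernel = np.ones(persistence)
    runs = np.convolve(growing.astype(float), kernel, mode="valid")
    hits = np.flatnonzero(runs >= persistence - 0.5)
    return int(hits[0]) + 1 if hits.size else None


def simulate_year(series: DailyClimateSeries, year: int,
                  params: VSParameters) -> GrowthYear:
    """Simulate one calendar year of daily growth rates.

    The daily rate is the day-length factor times the combined temperature
    and moisture responses; onset is the first day with a positive
    temperature response sustained for ``onset_persistence`` days.
    """
    t = series.year_tmean(year)
    n = len(t)
    g_t = ramp_response(t, params.t1, params.t2, params.t3, params.t4)

    if params.moisture_enabled:
        p = series.year_prcp(year)
        m = np.empty(n)
        state = 0.5  # half-full store at 1 January, reset every year
        for i in range(n):
            state = soil_moisture_step(state, p[i], t[i], params.bucket)
            m[i] = state
        g_m = ramp_response(m, params.m1, params.m2, params.m3, params.m4)
    else:
        g_m = np.ones(n)

    combined = np.minimum(g_t, g_m) if params.combine == "min" else g_t * g_m
    rate = daylength_factor(np.arange(1, n + 1), series.latitude, n_days=n) * combined
    onset = _find_onset(g_t > 0, params.onset_persistence)
    return GrowthYear(
        year=year,
        daily_rate=rate,
        onset_doy=onset,
        annual_increment=float(rate.sum()),
    )


def simulate_chronology(series: DailyClimateSeries, years: Iterable[int],
                        params: VSParameters) -> SimulatedChronology:
    """Simulate each year and standardize increments to mean one.

    If every increment is zero (climate never enters the growth window)
    the index is returned as zeros rather than dividing by zero.
    """
    years = np.asarray(sorted(years), dtype=int)
    if years.size == 0:
        raise ContractError("no years requested")
    growth = [simulate_year(series, int(y), params) for y in years]
    inc = np.array([g.annual_increment for g in growth])
    mean = inc.mean()
    index = inc / mean if mean > 0 else np.zeros_like(inc)
    return SimulatedChronology(
        years=years,
        index=index,
        onsets=[g.onset_doy for g in growth],
        increments=inc,
    )
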