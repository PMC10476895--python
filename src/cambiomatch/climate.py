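"""Daily climate ingestion, validation and seasonal aggregation.

The central container is :class:`DailyClimateSeries`: a calendar-complete
daily mean temperature series (optionally with precipitation) for one site.
All downstream computations — heat-unit sums, chilling-day counts, the
growth simulator — index into this container by calendar date, so the
constructor enforces strict contiguity and physically plausible values.

Seasonal means are always computed from the daily values (day-weighted),
never from monthly means, so month lengths are implicitly weighted. Winter
of year ``Y`` spans December of ``Y-1`` through February of ``Y``.
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, FormatError, GapError, IntegrityError

logger = logging.getLogger(__name__)

TMEAN_BOUNDS = (-60.0, 60.0)

#: (month, year offset) triples for the default seasons. Winter December
#: belongs to the previous calendar year.
SPRING_MONTHS: tuple[tuple[int, int], ...] = ((3, 0), (4, 0), (5, 0))
SUMMER_MONTHS: tuple[tuple[int, int], ...] = ((6, 0), (7, 0), (8, 0))
WINTER_MONTHS: tuple[tuple[int, int], ...] = ((12, -1), (1, 0), (2, 0))


@dataclass
class DailyClimateSeries:
    """Calendar-complete daily climate series for one site.

    Parameters
    ----------
    site_id:
        Identifier of the site the series belongs to.
    dates:
        Strictly increasing, gap-free daily ``DatetimeIndex``.
    tmean:
        Daily mean air temperature, deg C.
    prcp:
        Daily precipitation totals, mm; defaults to zero everywhere.
    latitude:
        Site latitude in decimal degrees; used for day-length modulation
        by the growth simulator.
    """

    site_id: str
    dates: pd.DatetimeIndex
    tmean: np.ndarray
    prcp: np.ndarray | None = None
    latitude: float = 45.0
    _year_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.tmean = np.asarray(self.tmean, dtype=float)
        if len(self.dates) != len(self.tmean):
            raise GapError("dates and tmean differ in length")
        if len(self.dates) == 0:
            raise GapError("empty climate series")
        deltas = np.diff(self.dates.values.astype("datetime64[D]").astype(int))
        if np.any(deltas <= 0):
            raise GapError(f"dates not strictly increasing for site {self.site_id!r}")
        if np.any(deltas != 1):
            missing = int(np.sum(deltas - 1))
            raise GapError(
                f"site {self.site_id!r}: {missing} missing calendar day(s) in series"
            )
        if not np.all(np.isfinite(self.tmean)):
            raise GapError(f"site {self.site_id!r}: non-finite tmean values")
        lo, hi = TMEAN_BOUNDS
        if self.tmean.min() < lo or self.tmean.max() > hi:
            raise GapError(
                f"site {self.site_id!r}: tmean outside plausible range {TMEAN_BOUNDS}"
            )
        if self.prcp is None:
            self.prcp = np.zeros_like(self.tmean)
        else:
            self.prcp = np.asarray(self.prcp, dtype=float)
            if len(self.prcp) != len(self.tmean):
                raise GapError("prcp and tmean differ in length")
            if np.any(self.prcp < 0) or not np.all(np.isfinite(self.prcp)):
                raise GapError(f"site {self.site_id!r}: invalid precipitation values")

    # -- indexing helpers ------------------------------------------------

    @property
    def start(self) -> pd.Timestamp:
        return self.dates[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.dates[-1]

    def covers(self, first: pd.Timestamp, last: pd.Timestamp) -> bool:
        """True when every day of ``[first, last]`` is in the series."""
        return bool(self.start <= pd.Timestamp(first) and pd.Timestamp(last) <= self.end)

    def _loc(self, day: pd.Timestamp) -> int:
        day = pd.Timestamp(day)
        idx = (day - self.start).days
        if idx < 0 or idx >= len(self.tmean):
            raise CoverageError(
                f"site {self.site_id!r}: {day.date()} outside series "
                f"[{self.start.date()}..{self.end.date()}]"
            )
        return int(idx)

    def window(self, first, last) -> np.ndarray:
        """Daily tmean values for the inclusive date window ``[first, last]``."""
        i0 = self._loc(first)
        i1 = self._loc(last)
        return self.tmean[i0 : i1 + 1]

    def year_tmean(self, year: int) -> np.ndarray:
        """Full calendar-year tmean (365 or 366 values), cached."""
        key = ("t", year)
        if key not in self._year_cache:
            self._year_cache[key] = self.window(
                pd.Timestamp(year=year, month=1, day=1),
                pd.Timestamp(year=year, month=12, day=31),
            )
        return self._year_cache[key]

    def year_prcp(self, year: int) -> np.ndarray:
        key = ("p", year)
        if key not in self._year_cache:
            i0 = self._loc(pd.Timestamp(year=year, month=1, day=1))
            i1 = self._loc(pd.Timestamp(year=year, month=12, day=31))
            self._year_cache[key] = self.prcp[i0 : i1 + 1]
        return self._year_cache[key]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "tmean": self.tmean, "prcp": self.prcp}
        )

    def to_csv(self, path) -> None:
        df = self.frame()
        df["date"] = df["date"].dt.strftime("%Y-%m-%d")
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class SeasonalMeans:
    """Day-weighted seasonal temperature means for one calendar year."""

    year: int
    spring: float
    summer: float
    winter: float


def read_daily_climate(
    source,
    site_id: str,
    latitude: float,
    max_gap_days: int = 0,
) -> DailyClimateSeries:
    """Read a climate CSV into a validated :class:`DailyClimateSeries`.

    The file must have either a ``date`` column (daily records) or a
    ``timestamp`` column (sub-daily records, which are averaged per calendar
    day; precipitation is summed). Gaps up to ``max_gap_days`` consecutive
    missing days are filled by linear interpolation; longer gaps raise
    :class:`GapError`. The default tolerance of zero demands a complete
    calendar record, the convention used for phenology years.
    """
    try:
        df = pd.read_csv(source)
    except (OSError, pd.errors.ParserError) as exc:  # pragma: no cover - passthrough
        raise FormatError(f"cannot read climate file {source!r}: {exc}") from exc

    cols = {c.lower(): c for c in df.columns}
    if "timestamp" in cols:
        try:
            ts = pd.to_datetime(df[cols["timestamp"]])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"unparseable timestamps in {source!r}: {exc}") from exc
        df = df.assign(_date=ts.dt.floor("D"))
        agg = {cols["tmean"]: "mean"}
        if "prcp" in cols:
            agg[cols["prcp"]] = "sum"
        daily = df.groupby("_date", as_index=True).agg(agg)
        daily.index.name = "date"
        daily = daily.rename(
            columns={cols["tmean"]: "tmean", cols.get("prcp", ""): "prcp"}
        )
    else:
        if "date" not in cols or "tmean" not in cols:
            raise FormatError(f"{source!r} lacks required 'date'/'tmean' columns")
        try:
            dates = pd.to_datetime(df[cols["date"]], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"unparseable dates in {source!r}: {exc}") from exc
        keep = {"tmean": df[cols["tmean"]].to_numpy(float)}
        if "prcp" in cols:
            keep["prcp"] = df[cols["prcp"]].to_numpy(float)
        daily = pd.DataFrame(keep, index=pd.DatetimeIndex(dates, name="date"))
        # conflicting duplicates are an integrity problem; identical ones collapse
        if daily.index.has_duplicates:
            spread = daily.groupby(level=0).agg(lambda s: s.max() - s.min())
            bad = spread.index[(spread > 1e-9).any(axis=1)]
            if len(bad):
                raise IntegrityError(
                    f"{source!r}: conflicting duplicate records for "
                    f"{[d.date().isoformat() for d in bad[:5]]}"
                )
            daily = daily.groupby(level=0).first()
    daily = daily.sort_index()

    full = pd.date_range(daily.index[0], daily.index[-1], freq="D")
    missing = full.difference(daily.index)
    if len(missing):
        # length of the longest run of consecutive missing days
        gaps = np.split(
            missing, np.where(np.diff(missing.values.astype("datetime64[D]").astype(int)) != 1)[0] + 1
        )
        longest = max(len(g) for g in gaps)
        if longest > max_gap_days:
            raise GapError(
                f"site {site_id!r}: {len(missing)} missing day(s), longest gap "
                f"{longest} > tolerance {max_gap_days}"
            )
        logger.warning(
            "site %r: interpolating %d missing day(s) across %d gap(s)",
            site_id, len(missing), len(gaps),
        )
        daily = daily.reindex(full)
        daily["tmean"] = daily["tmean"].interpolate(method="linear")
        if "prcp" in daily.columns:
            daily["prcp"] = daily["prcp"].fillna(0.0)

    return DailyClimateSeries(
        site_id=site_id,
        dates=pd.DatetimeIndex(daily.index),
        tmean=daily["tmean"].to_numpy(float),
        prcp=daily["prcp"].to_numpy(float) if "prcp" in daily.columns else None,
        latitude=latitude,
    )


def _season_slice(series: DailyClimateSeries, year: int,
                  months: Sequence[tuple[int, int]]) -> np.ndarray:
    parts = []
    for month, offset in months:
        y = year + offset
        last = calendar.monthrange(y, month)[1]
        parts.append(
            series.window(
                pd.Timestamp(year=y, month=month, day=1),
                pd.Timestamp(year=y, month=month, day=last),
            )
        )
    return np.concatenate(parts)


def seasonal_means(
    series: DailyClimateSeries,
    years: Iterable[int],
    spring_months: Sequence[tuple[int, int]] = SPRING_MONTHS,
    summer_months: Sequence[tuple[int, int]] = SUMMER_MONTHS,
    winter_months: Sequence[tuple[int, int]] = WINTER_MONTHS,
) -> list[SeasonalMeans]:
    """Day-weighted spring (MAM), summer (JJA) and winter (DJF) means.

    Winter of year ``Y`` uses December of ``Y-1``; requesting it for a
    series starting in January of ``Y`` raises :class:`CoverageError`.
    """
    out = []
    for year in years:
        out.append(
            SeasonalMeans(
                year=int(year),
                spring=float(np.mean(_season_slice(series, year, spring_months))),
                summer=float(np.mean(_season_slice(series, year, summer_months))),
                winter=float(np.mean(_season_slice(series, year, winter_months))),
            )
        )
    return out


def seasonal_frame(means: list[SeasonalMeans]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in means]).set_index("year")
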