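"""Ring-width ingestion, detrending, chronology building and moving
growth-climate correlations.

Raw ring widths carry strong age/size trends; dividing each series by a
fitted growth curve yields dimensionless indices with mean ~1, and the
per-year mean of indices across series is the site chronology. Three
detrending curves are provided: a cubic-smoothing-spline analogue (a
second-difference penalized smoother whose 50% amplitude cutoff defaults
to two-thirds of the series length, the de-facto dendro standard), a
non-increasing modified negative exponential with straight-line and mean
fallbacks, and a horizontal mean line.

Tucson/RWL decadal files are read and written directly, honoring the
999 (0.01 mm) and -9999 (0.001 mm) stop-marker dialects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import AlignmentError, ContractError, FormatError

logger = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 25  # meta-analysis inclusion threshold, configurable


@dataclass
class RingWidthSeries:
    """One measured ring-width series over consecutive calendar years."""

    series_id: str
    years: np.ndarray
    widths: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.widths = np.asarray(self.widths, dtype=float)
        if len(self.years) != len(self.widths):
            raise ContractError("years and widths differ in length")
        if len(self.years) == 0:
            raise ContractError("empty ring-width series")
        if np.any(np.diff(self.years) != 1):
            raise ContractError(f"series {self.series_id!r}: years not consecutive")
        if np.any(self.widths <= 0) or not np.all(np.isfinite(self.widths)):
            raise ContractError(f"series {self.series_id!r}: widths must be > 0")


@dataclass
class IndexedSeries:
    """A detrended (dimensionless) ring-width index series."""

    series_id: str
    years: np.ndarray
    index: np.ndarray


@dataclass
class Chronology:
    """Mean indexed standardized series with per-year sample depth."""

    site_id: str
    life_form: str
    years: np.ndarray
    index: np.ndarray
    sample_depth: np.ndarray


@dataclass
class MovingCorrelationResult:
    """Sliding-window Pearson correlations labelled by central year."""

    window_length: int
    center_years: np.ndarray
    r_values: np.ndarray
    p_values: np.ndarray
    sig_level: float = 0.05


# ---------------------------------------------------------------------------
# Tucson / RWL I/O


def _parse_rwl_value(tok: str, line_no: int) -> int:
    try:
        return int(tok)
    except ValueError as exc:
        raise FormatError(f"RWL line {line_no}: bad value {tok!r}") from exc


def read_rwl(source, min_length: int = 0) -> list[RingWidthSeries]:
    """Parse a Tucson/RWL decadal file.

    The stop marker determines measurement precision: 999 means 0.01 mm
    units, -9999 means 0.001 mm. Series shorter than ``min_length`` years
    are dropped with a logged notice (pass 0 to keep everything).
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()

    raw: dict[str, list[tuple[int, int]]] = {}
    for line_no, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        sid = line[:8].strip()
        rest = line[8:].split()
        if not sid or len(rest) < 2:
            raise FormatError(f"RWL line {line_no}: malformed decade line")
        year = _parse_rwl_value(rest[0], line_no)
        vals = [_parse_rwl_value(tok, line_no) for tok in rest[1:]]
        bucket = raw.setdefault(sid, [])
        bucket.extend((year + offset, v) for offset, v in enumerate(vals))

    out = []
    for sid, pairs in raw.items():
        # only the final value of a series may be a stop marker: a data
        # value of 999 (0.999 mm in the 0.001 dialect) must not truncate
        divisor = 100.0
        if pairs and pairs[-1][1] == -9999:
            divisor = 1000.0
            pairs = pairs[:-1]
        elif pairs and pairs[-1][1] == 999:
            pairs = pairs[:-1]
        years = np.array([y for y, _ in pairs])
        widths = np.array([v for _, v in pairs], dtype=float) / divisor
        if len(years) < min_length:
            logger.info("dropping series %r: %d < %d years", sid, len(years), min_length)
            continue
        out.append(RingWidthSeries(series_id=sid, years=years, widths=widths))
    return out


def write_rwl(series_list: Sequence[RingWidthSeries], path,
              precision: float = 0.01) -> None:
    """Write series in Tucson decadal format (0.01 or 0.001 mm dialects)."""
    if precision == 0.01:
        scale, marker = 100.0, 999
    elif precision == 0.001:
        scale, marker = 1000.0, -9999
    else:
        raise ContractError("precision must be 0.01 or 0.001 mm")
    with open(path, "w") as fh:
        for s in series_list:
            if len(s.series_id) > 8:
                raise ContractError(
                    f"series id {s.series_id!r} exceeds the 8-character Tucson field"
                )
            values = [int(round(w * scale)) for w in s.widths] + [marker]
            years = list(s.years) + [s.years[-1] + 1]
            i = 0
            while i < len(values):
                year = years[i]
                row_end = ((year // 10) + 1) * 10  # decade boundary
                n = min(row_end - year, len(values) - i)
                row = values[i : i + n]
                fh.write(f"{s.series_id:<8}{year:4d}" +
                         "".join(f"{v:6d}" for v in row) + "\n")
                i += n


def read_ringwidth_csv(source, min_length: int = 0) -> list[RingWidthSeries]:
    """Long-format alternative: columns series_id, year, width_mm."""
    df = pd.read_csv(source, comment="#")
    df.columns = [c.lower() for c in df.columns]
    wcol = "width_mm" if "width_mm" in df.columns else "width"
    out = []
    for sid, grp in df.groupby("series_id", sort=True):
        grp = grp.sort_values("year")
        if len(grp) < min_length:
            continue
        out.append(
            RingWidthSeries(
                series_id=str(sid),
                years=grp["year"].to_numpy(int),
                widths=grp[wcol].to_numpy(float),
            )
        )
    return out


def write_ringwidth_csv(series_list: Sequence[RingWidthSeries], path) -> None:
    rows = [
        {"series_id": s.series_id, "year": int(y), "width_mm": float(w)}
        for s in series_list
        for y, w in zip(s.years, s.widths)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# detrending


def _penalized_spline(y: np.ndarray, cutoff: float) -> np.ndarray:
    """Second-difference penalized smoother (discrete smoothing spline).

    The penalty weight is chosen so the filter's amplitude response is 50%
    at wavelength ``cutoff`` (years): lambda = (2 - 2 cos(2 pi / cutoff))^-2.
    """
    n = len(y)
    if n < 4:
        return np.full(n, y.mean())
    omega = 2.0 * np.pi / max(cutoff, 2.0)
    lam = (2.0 - 2.0 * np.cos(omega)) ** -2
    d = np.zeros((n - 2, n))
    rows = np.arange(n - 2)
    d[rows, rows] = 1.0
    d[rows, rows + 1] = -2.0
    d[rows, rows + 2] = 1.0
    a = np.eye(n) + lam * d.T @ d
    return np.linalg.solve(a, y)


def _negexp_curve(y: np.ndarray) -> tuple[np.ndarray, str]:
    """Modified negative exponential a*exp(-b t)+k with line/mean fallback."""
    n = len(y)
    t = np.arange(n, dtype=float)

    def f(t_, a, b, k):
        return a * np.exp(-b * t_) + k

    try:
        p0 = (max(y[0] - y[-1], 1e-3), 1.0 / max(n, 1), max(y[-1], 1e-3))
        popt, _ = optimize.curve_fit(
            f, t, y, p0=p0,
            bounds=([1e-12, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=5000,
        )
        fit = f(t, *popt)
        if np.all(fit > 0):
            return fit, "negexp"
    except (RuntimeError, ValueError):
        pass
    # straight-line fallback, accepted only if non-increasing and positive
    slope, intercept = np.polyfit(t, y, 1)
    line = slope * t + intercept
    if slope <= 0 and np.all(line > 0):
        logger.warning("negexp fit failed; using straight-line fallback")
        return line, "line"
    logger.warning("negexp and line fallbacks invalid; using horizontal mean")
    return np.full(n, y.mean()), "mean"


def detrend_series(
    series: RingWidthSeries,
    method: str = "spline",
    cutoff_frac: float = 2.0 / 3.0,
    rescale: bool = True,
) -> IndexedSeries:
    """Divide widths by a fitted growth curve to get dimensionless indices.

    ``spline`` uses the penalized smoother with a 50% cutoff at
    ``cutoff_frac`` of the series length; ``negexp`` the modified negative
    exponential (with documented fallbacks); ``mean`` the horizontal mean.
    With ``rescale`` (default) the index is normalized to mean exactly 1.
    """
    y = series.widths
    if method == "spline":
        if len(y) < 10:
            raise ContractError("spline detrending needs >= 10 years")
        fit = _penalized_spline(y, cutoff_frac * len(y))
    elif method == "negexp":
        fit, _ = _negexp_curve(y)
    elif method == "mean":
        fit = np.full(len(y), y.mean())
    else:
        raise ContractError(f"unknown detrending method {method!r}")
    fit = np.maximum(fit, 1e-6 * y.mean())
    index = y / fit
    if rescale:
        index = index / index.mean()
    return IndexedSeries(series_id=series.series_id, years=series.years.copy(),
                         index=index)


def tukey_biweight_mean(x: np.ndarray, c: float = 9.0) -> float:
    """Tukey's biweight robust location (median/MAD start, c = 9)."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    s = np.median(np.abs(x - med))
    if s < 1e-12:
        return float(med)
    u = (x - med) / (c * s)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    return float(np.sum(w * x) / np.sum(w))


def build_chronology(
    indexed: Sequence[IndexedSeries],
    site_id: str = "",
    life_form: str = "",
    robust: bool = False,
) -> Chronology:
    """Average index series year-by-year into a site chronology.

    Uses the arithmetic mean, or Tukey's biweight robust mean when
    ``robust``; sample depth records how many series cover each year.
    Multiple series must overlap somewhere, otherwise averaging them into
    one chronology is meaningless.
    """
    if not indexed:
        raise ContractError("no indexed series supplied")
    all_years = np.arange(
        min(s.years[0] for s in indexed), max(s.years[-1] for s in indexed) + 1
    )
    table = np.full((len(indexed), len(all_years)), np.nan)
    for i, s in enumerate(indexed):
        table[i, s.years - all_years[0]] = s.index
    depth = np.sum(~np.isnan(table), axis=0)
    if len(indexed) > 1 and depth.max() < 2:
        raise ContractError("series never overlap; cannot build a chronology")
    keep = depth >= 1
    values = np.empty(int(keep.sum()))
    for j, col in enumerate(np.flatnonzero(keep)):
        vals = table[:, col]
        vals = vals[~np.isnan(vals)]
        values[j] = tukey_biweight_mean(vals) if robust else vals.mean()
    return Chronology(
        site_id=site_id,
        life_form=life_form,
        years=all_years[keep],
        index=values,
        sample_depth=depth[keep],
    )


# ---------------------------------------------------------------------------
# moving correlations


def moving_correlation(
    chron: Chronology,
    seasonal_years: Sequence[int],
    seasonal_values: Sequence[float],
    window: int = 21,
) -> MovingCorrelationResult:
    """Sliding-window Pearson correlations between chronology and climate.

    Windows advance one year at a time and are labelled by their central
    year; the two series must align exactly over the chronology years.
    """
    seasonal = dict(zip(np.asarray(seasonal_years, int), np.asarray(seasonal_values, float)))
    missing = [int(y) for y in chron.years if int(y) not in seasonal]
    if missing:
        raise AlignmentError(f"seasonal series lacks years {missing[:5]}")
    clim = np.array([seasonal[int(y)] for y in chron.years])
    n = len(chron.years)
    if n < window:
        raise ContractError(f"need >= {window} years, got {n}")
    centers, rs, ps = [], [], []
    half = window // 2
    for i in range(n - window + 1):
        a = chron.index[i : i + window]
        b = clim[i : i + window]
        if np.array_equal(a, b):
            r, p = 1.0, 0.0
        else:
            r, p = stats.pearsonr(a, b)
        centers.append(int(chron.years[i + half]))
        rs.append(float(r))
        ps.append(float(p))
    return MovingCorrelationResult(
        window_length=window,
        center_years=np.array(centers),
        r_values=np.array(rs),
        p_values=np.array(ps),
    )


def aggregate_moving_correlations(
    results: Sequence[MovingCorrelationResult],
) -> pd.DataFrame:
    """Mean r with standard error across sites, per central year.

    This is the meta-analysis summary: each site contributes its window
    correlation, and points are the cross-site mean with SE.
    """
    if not results:
        raise ContractError("no moving-correlation results to aggregate")
    rows = []
    for res in results:
        for year, r in zip(res.center_years, res.r_values):
            rows.append({"center_year": int(year), "r": float(r)})
    df = pd.DataFrame(rows)
    agg = df.groupby("center_year")["r"].agg(["mean", "sem", "count"]).reset_index()
    return agg.rename(columns={"mean": "mean_r", "sem": "se", "count": "n_sites"})
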