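"""Phenology-response regressions and correlations.

The onset-versus-spring-temperature relation at cold treeline sites is
non-linear; it is linearized by transforming spring temperature x (deg C,
x < 1) to x' = log10(1 - x) and regressing onset day of year on x' by
ordinary least squares. The reported "days per deg C" is the local
derivative of the back-transformed model at the sample-mean spring
temperature,

    dy/dx = -slope' / ((1 - x_bar) ln 10),

which is the chain rule applied to the fitted line. Slopes of two life
forms are contrasted with the classic pooled two-slope t test (equal to
the interaction t in a pooled regression with group-specific intercepts
and slopes, df = n1 + n2 - 4). Partial correlations are Pearson
correlations of residuals after regressing both variables on the
controls. The projected phenological mismatch under a warming scenario
is the difference of the two life forms' local days-per-degC slopes times
the warming, positive when shrubs delay relative to trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ContractError, DegenerateInputError, DomainError, RankError

LN10 = np.log(10.0)


@dataclass
class ResponseFit:
    """OLS fit of onset DOY on linearized spring temperature."""

    life_form: str
    slope: float            # days per unit of x' = log10(1 - x)
    intercept: float
    slope_se: float
    r_squared: float
    n: int
    mean_spring_t: float
    days_per_degc: float    # local back-transformed slope at mean_spring_t
    p_value: float

    def predict(self, spring_t) -> np.ndarray:
        """Back-transformed prediction curve (days) for spring temps < 1."""
        xprime = linearize_temp(spring_t)
        return self.intercept + self.slope * xprime


@dataclass
class SlopeContrast:
    """Pooled two-slope t test between life forms."""

    t_statistic: float
    p_value: float
    df: int
    slope_difference: float


def linearize_temp(x, labels: Sequence | None = None):
    """Transform spring temperature x (< 1 deg C) to x' = log10(1 - x).

    Values at or above 1 deg C are outside the transform's domain and
    raise :class:`DomainError` naming the offending records; they are
    never silently dropped.
    """
    arr = np.asarray(x, dtype=float)
    bad = np.flatnonzero(~(arr < 1.0))
    if bad.size:
        names = [labels[i] for i in bad[:5]] if labels is not None else bad[:5].tolist()
        raise DomainError(
            f"spring temperature >= 1 degC for records {names}; "
            "log10(1 - x) undefined"
        )
    out = np.log10(1.0 - arr)
    return float(out) if out.ndim == 0 else out


def fit_response(
    onset_doy: Sequence[float],
    spring_t: Sequence[float],
    life_form: str = "",
    labels: Sequence | None = None,
) -> ResponseFit:
    """OLS of onset on linearized spring temperature for one life form."""
    y = np.asarray(onset_doy, dtype=float)
    x = np.asarray(spring_t, dtype=float)
    if y.size != x.size:
        raise ContractError("onset and spring temperature differ in length")
    if y.size < 3:
        raise ContractError("need at least 3 records")
    xp = linearize_temp(x, labels=labels)
    res = stats.linregress(xp, y)
    xbar = float(x.mean())
    # chain rule: dy/dx = slope * d(log10(1-x))/dx = -slope / ((1-x) ln 10)
    days_per_degc = -res.slope / ((1.0 - xbar) * LN10)
    return ResponseFit(
        life_form=life_form,
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n=int(y.size),
        mean_spring_t=xbar,
        days_per_degc=float(days_per_degc),
        p_value=float(res.pvalue),
    )


def _ols_parts(x: np.ndarray, y: np.ndarray):
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    slope = float(np.sum(xc * (y - y.mean())) / sxx)
    resid = y - (y.mean() + slope * xc)
    return slope, sxx, float(np.sum(resid**2))


def compare_slopes(
    onset_a: Sequence[float], spring_a: Sequence[float],
    onset_b: Sequence[float], spring_b: Sequence[float],
) -> SlopeContrast:
    """Pooled two-slope t test on the transformed scale.

    Equivalent to the interaction t statistic of a pooled regression with
    group-specific intercepts and slopes; antisymmetric in its arguments.
    """
    ya, xa = np.asarray(onset_a, float), linearize_temp(np.asarray(spring_a, float))
    yb, xb = np.asarray(onset_b, float), linearize_temp(np.asarray(spring_b, float))
    if ya.size < 3 or yb.size < 3:
        raise ContractError("each group needs at least 3 records")
    slope_a, sxx_a, sse_a = _ols_parts(xa, ya)
    slope_b, sxx_b, sse_b = _ols_parts(xb, yb)
    df = ya.size + yb.size - 4
    s2 = (sse_a + sse_b) / df
    se = np.sqrt(s2 * (1.0 / sxx_a + 1.0 / sxx_b))
    t = (slope_a - slope_b) / se
    return SlopeContrast(
        t_statistic=float(t),
        p_value=float(2 * stats.t.sf(abs(t), df)),
        df=int(df),
        slope_difference=float(slope_a - slope_b),
    )


def onset_growth_correlation(
    onset_doy: Sequence[float], ring_index: Sequence[float]
) -> tuple[float, float, float]:
    """Pearson r, two-sided p and OLS slope of ring index on onset day."""
    y = np.asarray(ring_index, float)
    x = np.asarray(onset_doy, float)
    if x.size != y.size or x.size < 3:
        raise ContractError("need >= 3 paired records")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance in onset or ring index")
    r, p = stats.pearsonr(x, y)
    slope = float(np.polyfit(x, y, 1)[0])
    return float(r), float(p), slope


def partial_correlation(
    x: Sequence[float], y: Sequence[float],
    controls: Sequence[Sequence[float]] | None = None,
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given control variables.

    Computed as the correlation of the residuals of x and y after OLS on
    the controls (with intercept); with no controls this is exactly the
    plain Pearson correlation. p uses the t transform with
    df = n - n_controls - 2.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if controls is None or (hasattr(controls, "__len__") and len(controls) == 0):
        if x.size < 3:
            raise ContractError("need n >= 3")
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    z = np.column_stack([np.asarray(c, float) for c in controls])
    k = z.shape[1]
    if x.size <= k + 2:
        raise ContractError(f"need n > n_controls + 2 = {k + 2}")
    design = np.column_stack([np.ones(len(x)), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise RankError("collinear control variables")
    bx, *_ = np.linalg.lstsq(design, x, rcond=None)
    by, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ bx
    ry = y - design @ by
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        raise DegenerateInputError("residuals have zero variance")
    r = float(np.clip(np.sum(rx * ry) / denom, -1.0, 1.0))
    df = x.size - k - 2
    t = r * np.sqrt(df / max(1.0 - r * r, 1e-15))
    return r, float(2 * stats.t.sf(abs(t), df))


def project_mismatch(fit_shrub, fit_tree, delta_t: float) -> float:
    """Projected onset divergence (days) after warming by ``delta_t`` deg C.

    Accepts :class:`ResponseFit` objects or bare days-per-degC slopes;
    positive values mean shrubs delay relative to trees.
    """
    shrub = getattr(fit_shrub, "days_per_degc", fit_shrub)
    tree = getattr(fit_tree, "days_per_degc", fit_tree)
    return float((shrub - tree) * delta_t)
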