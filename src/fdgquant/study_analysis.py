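"""Cohort-level analyses: tumor growth and glucose-dependence screens.

Tumor growth is modelled as exponential; the doubling time is estimated by
ordinary least squares of log-volume on day (Td = ln 2 / slope), fitted per
animal and then averaged over the cohort.  The glucose screens are simple
linear regressions of a kinetic metric (Ki, MRGlu, SUV) on blood glucose with
a two-sided t-test of zero slope — the comparison that motivates choosing
MRGlu (glucose-independent) over Ki (inversely glucose-dependent) as the
primary outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, SingularFitError, ValidationError


@dataclass(frozen=True)
class GrowthFit:
    """Log-linear exponential-growth fit for one volume series."""

    doubling_time_days: float
    growth_rate_per_day: float
    v0_mm3: float
    r_squared: float
    n_points: int
    nonpositive_slope: bool = False

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValidationError("a growth fit needs at least 2 points")


@dataclass(frozen=True)
class CorrelationResult:
    """Simple linear regression of a metric on blood glucose."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValidationError("r_squared must lie in [0, 1]")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError("p_value must lie in (0, 1]")


def fit_doubling_time(days: np.ndarray, volumes_mm3: np.ndarray) -> GrowthFit:
    """OLS of ln(volume) on day; doubling time = ln 2 / slope.

    A nonpositive slope (shrinking series) yields an infinite doubling time
    with the ``nonpositive_slope`` flag set rather than an error.
    """
    days = np.asarray(days, dtype=float)
    vols = np.asarray(volumes_mm3, dtype=float)
    if days.shape != vols.shape or days.ndim != 1:
        raise ValidationError("days and volumes must be matching 1-D arrays")
    if np.unique(days).size < 2:
        raise InsufficientDataError("need at least 2 distinct measurement days")
    if np.any(vols <= 0):
        raise ValidationError("volumes must be positive for a log-linear fit")
    fit = stats.linregress(days, np.log(vols))
    slope = float(fit.slope)
    r2 = float(fit.rvalue**2) if np.ptp(np.log(vols)) > 0 else 1.0
    if slope <= 0:
        return GrowthFit(
            doubling_time_days=np.inf,
            growth_rate_per_day=slope,
            v0_mm3=float(np.exp(fit.intercept)),
            r_squared=r2,
            n_points=int(days.size),
            nonpositive_slope=True,
        )
    return GrowthFit(
        doubling_time_days=float(np.log(2.0) / slope),
        growth_rate_per_day=slope,
        v0_mm3=float(np.exp(fit.intercept)),
        r_squared=r2,
        n_points=int(days.size),
    )


def fit_cohort_doubling_time(records: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Per-animal log-linear fits, then the cohort mean doubling time.

    ``records`` is a tidy frame with columns subject_id, day, volume_mm3.
    Animals with a nonpositive growth slope are excluded from the mean (their
    doubling time is infinite) but reported in the per-animal table.
    """
    rows = []
    for subject, grp in records.groupby("subject_id", sort=True):
        fit = fit_doubling_time(grp["day"].to_numpy(), grp["volume_mm3"].to_numpy())
        rows.append(
            {
                "subject_id": subject,
                "doubling_time_days": fit.doubling_time_days,
                "growth_rate_per_day": fit.growth_rate_per_day,
                "v0_mm3": fit.v0_mm3,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
            }
        )
    per_animal = pd.DataFrame(rows)
    finite = per_animal["doubling_time_days"].replace(np.inf, np.nan).dropna()
    if finite.empty:
        raise InsufficientDataError("no animal shows positive growth")
    return float(finite.mean()), per_animal


def regress_metric_on_glucose(
    glucose_mmol_l: np.ndarray, metric_values: np.ndarray
) -> CorrelationResult:
    """Linear regression of a kinetic metric on blood glucose.

    Returns slope, intercept, R² and the two-sided p-value of the t-test of
    slope = 0.
    """
    x = np.asarray(glucose_mmol_l, dtype=float)
    y = np.asarray(metric_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("glucose and metric arrays must be matching 1-D")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("regression inputs must be finite")
    if np.ptp(x) == 0:
        raise SingularFitError("no variance in blood glucose; slope undefined")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2) if np.ptp(y) > 0 else 0.0
    return CorrelationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        p_value=float(fit.pvalue) if np.ptp(y) > 0 else 1.0,
        n=int(x.size),
    )


def weekly_summary(
    results: pd.DataFrame,
    value_col: str = "value",
    by: tuple[str, ...] = ("week", "organ", "metric"),
) -> pd.DataFrame:
    """Per-stratum mean, SD (n−1 denominator), CV and n.

    CV = SD/mean is reported as NaN for zero-mean strata.  Empty strata
    simply yield no row.
    """
    if results.empty:
        return pd.DataFrame(columns=list(by) + ["mean", "sd", "cv", "n"])

    def _agg(grp: pd.Series) -> pd.Series:
        vals = grp.to_numpy(dtype=float)
        mean = vals.mean()
        sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        return pd.Series(
            {"mean": mean, "sd": sd, "cv": sd / mean if mean != 0 else np.nan,
             "n": vals.size}
        )

    out = (
        results.groupby(list(by), sort=True)[value_col]
        .apply(_agg)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
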