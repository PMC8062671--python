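"""Temporal structure of fire catalogs: annual series, segmented trend
regression around a fixed breakpoint, and monthly seasonality profiles.

Annual series are zero-filled over the catalog period so that fire-free
years enter the regressions as genuine zeros rather than missing rows.
The segmented regression fits the two sides of a *fixed* breakpoint year
independently (no continuity constraint at the join): the question is how
the trend before the breakpoint compares with the trend after it, not
where the breakpoint is.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .catalog import EmptyCatalogError, FireCatalog, cause_binary

__all__ = [
    "GROUPS",
    "SegmentFit",
    "SegmentedFit",
    "annual_series",
    "segmented_regression",
    "monthly_profile",
    "peak_month",
    "season_months",
]

#: Catalog subsets a series may be computed over.
GROUPS = ("all", "large", "small", "natural", "human")

DEFAULT_SIZE_THRESHOLD = 500.0  # acres


def _group_mask(catalog: FireCatalog, group: str, threshold: float) -> list[bool]:
    if group == "all":
        return [True] * len(catalog)
    if group == "large":
        return [r.size_acres >= threshold for r in catalog]
    if group == "small":
        return [r.size_acres < threshold for r in catalog]
    if group in ("natural", "human"):
        return [cause_binary(r.cause) == group for r in catalog]
    raise ValueError(f"unknown group {group!r}; choose from {GROUPS}")


def annual_series(
    catalog: FireCatalog,
    measure: str = "frequency",
    group: str = "all",
    threshold: float = DEFAULT_SIZE_THRESHOLD,
) -> pd.Series:
    """Annual fire counts or burned-area totals, zero-filled over the period.

    ``measure`` is ``"frequency"`` (fires per year) or ``"burned_area"``
    (acres per year); ``group`` selects a catalog subset (:data:`GROUPS`),
    with large/small split at ``threshold`` acres.
    """
    if len(catalog) == 0:
        raise EmptyCatalogError("cannot build an annual series from an empty catalog")
    if measure not in ("frequency", "burned_area"):
        raise ValueError(f"unknown measure {measure!r}")
    mask = _group_mask(catalog, group, threshold)
    years = np.array([r.year for r, m in zip(catalog, mask) if m])
    vals = (
        np.ones_like(years, dtype=float)
        if measure == "frequency"
        else np.array([r.size_acres for r, m in zip(catalog, mask) if m])
    )
    lo, hi = catalog.period
    index = pd.RangeIndex(lo, hi + 1, name="year")
    series = pd.Series(0.0, index=index, name=f"{measure}_{group}")
    if years.size:
        sums = pd.Series(vals).groupby(years).sum()
        series.loc[sums.index] = sums.values
    return series


@dataclass(frozen=True)
class SegmentFit:
    """OLS fit of value on year over one segment."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    years: np.ndarray
    fitted: np.ndarray
    band_lower: np.ndarray  # 95% mean-prediction band
    band_upper: np.ndarray


@dataclass(frozen=True)
class SegmentedFit:
    breakpoint: int
    before: SegmentFit
    after: SegmentFit


def _ols_segment(years: np.ndarray, values: np.ndarray, label: str) -> SegmentFit:
    if years.size < 3:
        raise ValueError(f"segment {label!r} too short for regression ({years.size} years)")
    X = sm.add_constant(years.astype(float))
    res = sm.OLS(values, X).fit()
    pred = res.get_prediction(X)
    band = pred.conf_int(alpha=0.05)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(res.rsquared)  # a constant series has no explainable variance
    return SegmentFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=r2 if np.isfinite(r2) else 0.0,
        p_value=float(res.pvalues[1]),
        years=years.copy(),
        fitted=np.asarray(pred.predicted_mean),
        band_lower=band[:, 0],
        band_upper=band[:, 1],
    )


def segmented_regression(series: pd.Series, breakpoint: int = 2000) -> SegmentedFit:
    """Independent OLS trend lines before and after a fixed breakpoint year.

    The first segment covers years < breakpoint, the second years >=
    breakpoint.  Each segment reports slope, intercept, R², the two-sided
    p-value of the slope t-test, and a 95% mean-prediction confidence band.
    """
    years = np.asarray(series.index, dtype=int)
    values = np.asarray(series.values, dtype=float)
    before = _ols_segment(years[years < breakpoint], values[years < breakpoint], "before")
    after = _ols_segment(years[years >= breakpoint], values[years >= breakpoint], "after")
    return SegmentedFit(breakpoint=int(breakpoint), before=before, after=after)


def monthly_profile(
    catalog: FireCatalog,
    measure: str = "frequency",
    group: str = "all",
    threshold: float = DEFAULT_SIZE_THRESHOLD,
) -> pd.DataFrame:
    """Per-(year, month) totals suitable for seasonal box statistics.

    Returns a DataFrame indexed by year with the twelve months as columns,
    zero-filled, so that each column collects one value per year and box
    statistics (median, quartiles) can be taken across years downstream.
    """
    if len(catalog) == 0:
        raise EmptyCatalogError("cannot build a monthly profile from an empty catalog")
    if measure not in ("frequency", "burned_area"):
        raise ValueError(f"unknown measure {measure!r}")
    mask = _group_mask(catalog, group, threshold)
    lo, hi = catalog.period
    table = pd.DataFrame(
        0.0, index=pd.RangeIndex(lo, hi + 1, name="year"), columns=pd.RangeIndex(1, 13, name="month")
    )
    for rec, m in zip(catalog, mask):
        if m:
            table.loc[rec.year, rec.month] += 1.0 if measure == "frequency" else rec.size_acres
    return table


def peak_month(profile: pd.DataFrame) -> int:
    """Month maximizing the across-year mean; ties break to the earlier month."""
    means = profile.mean(axis=0)
    if float(means.max()) == 0.0:
        raise ValueError("all-zero profile has no defined peak month")
    return int(means.idxmax())  # idxmax returns the first (earliest) maximum


def season_months(profile: pd.DataFrame, fraction: float = 0.5) -> tuple[int, int]:
    """(first month, length) of the fire season.

    The season starts at the first month whose across-year mean exceeds
    ``fraction`` of the peak-month mean and runs through the last such
    month.  Descriptive only: the rule is a convention, not an inference.
    """
    means = profile.mean(axis=0)
    peak = float(means.max())
    if peak == 0.0:
        raise ValueError("all-zero profile has no season")
    active = means[means >= fraction * peak].index
    return int(active.min()), int(active.max() - active.min() + 1)
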