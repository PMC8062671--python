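"""Heavy-tailed fire-size distributions: fitting, goodness of fit, and
threshold selection.

Burned-area distributions are strongly right-skewed: most fires are small
while a handful of very large events dominate the total area.  Five
candidate families are supported, each in the parameterization below
(``x`` is burned area in acres, ``alpha`` the shape, ``beta`` the scale):

===============  ==========================================================
gamma            f(x) = beta^alpha / Gamma(alpha) * x^(alpha-1) e^(-beta x)
                 (``beta`` is a *rate*, 1/acres)
lognormal        f(x) = 1/(sqrt(2 pi) beta x) exp(-(ln x - alpha)^2/(2 beta^2))
                 (``alpha`` = log-mean, ``beta`` = log-sd)
pareto           f(x) = alpha beta^alpha / x^(alpha+1),  x >= beta (Type I)
truncated_pareto f(x) = alpha beta^alpha x^(-alpha-1) / (1 - (beta/H)^alpha),
                 beta <= x <= H
weibull          f(x) = (alpha/beta) (x/beta)^(alpha-1) e^(-(x/beta)^alpha)
===============  ==========================================================

The Pareto MLE is the closed-form Hill estimator with ``beta`` at the
sample minimum.  The truncated Pareto follows the conditional MLE: the
truncation bound ``H`` is pinned at the sample maximum, ``beta`` at the
sample minimum, and the shape solves the score equation

    n/alpha + n r^alpha ln r / (1 - r^alpha) = sum ln(x_i / beta),
    r = beta / H

by bracketed root-finding.  ``H`` is treated as fixed (not a free
parameter) when counting parameters for AIC, so every family carries
k = 2 free parameters.

A Lomax (shifted Pareto) variant is available behind ``family="lomax"``
for comparison with software that parameterizes the Pareto with support
starting at zero; the Type I form above is the default and the one used
throughout the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "LOG_FAMILIES",
    "FitError",
    "DegeneracyError",
    "DistributionFit",
    "GofReport",
    "MeanExcessCurve",
    "ThresholdSelection",
    "fit_distribution",
    "goodness_of_fit",
    "mean_excess_curve",
    "select_threshold",
    "compare_families",
]

#: Families fitted on the natural (acre) scale.
FAMILIES = ("gamma", "lognormal", "pareto", "truncated_pareto", "weibull")

#: Families that may be fitted to log-transformed sizes.
LOG_FAMILIES = ("gamma", "lognormal", "weibull")

_MIN_N = 10


class FitError(RuntimeError):
    """Fitting failed (non-convergence, invalid data, ...)."""


class DegeneracyError(FitError):
    """The sample is degenerate for the requested family (e.g. zero spread)."""


@dataclass(frozen=True)
class DistributionFit:
    """Maximum-likelihood fit of one family.

    ``shape``/``scale`` follow the parameterizations in the module
    docstring; ``h`` is the upper truncation bound (truncated Pareto only).
    ``log_transformed`` marks fits performed on ln(size).
    """

    family: str
    shape: float
    scale: float
    loglik: float
    n: int
    support_min: float
    h: float | None = None
    log_transformed: bool = False

    @property
    def k(self) -> int:
        """Number of free parameters (H is pinned at the sample maximum)."""
        return 2

    def cdf(self, x: np.ndarray) -> np.ndarray:
        """CDF of the fitted family, on the same scale the fit was done."""
        x = np.asarray(x, dtype=float)
        a, b = self.shape, self.scale
        if self.family == "gamma":
            return stats.gamma.cdf(x, a, scale=1.0 / b)
        if self.family == "lognormal":
            return stats.norm.cdf((np.log(x) - a) / b)
        if self.family == "pareto":
            return np.where(x < b, 0.0, 1.0 - (b / np.maximum(x, b)) ** a)
        if self.family == "truncated_pareto":
            r = b / self.h
            num = 1.0 - (b / np.clip(x, b, self.h)) ** a
            return np.clip(num / (1.0 - r**a), 0.0, 1.0)
        if self.family == "weibull":
            return stats.weibull_min.cdf(x, a, scale=b)
        if self.family == "lomax":
            return stats.lomax.cdf(x, a, scale=b)
        raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class GofReport:
    """Goodness-of-fit scores; smaller is better for all three."""

    aic: float
    ks: float
    cvm: float


@dataclass(frozen=True)
class MeanExcessCurve:
    """Mean excess e(u) = mean(x - u | x > u) at ascending thresholds u."""

    thresholds: np.ndarray
    mean_excess: np.ndarray
    n_exceed: np.ndarray


@dataclass(frozen=True)
class ThresholdSelection:
    """Change-point threshold choice plus the tail line for inspection."""

    threshold: float
    slope: float
    intercept: float
    objective: dict[float, float]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _check_sizes(sizes: np.ndarray) -> np.ndarray:
    x = np.asarray(sizes, dtype=float).ravel()
    if x.size < _MIN_N:
        raise FitError(f"need at least {_MIN_N} observations, got {x.size}")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise FitError("sizes must be finite and strictly positive")
    return x


def _truncated_pareto_alpha(x: np.ndarray, beta: float, h: float) -> float:
    """Solve the conditional-MLE score equation for the truncated Pareto shape."""
    n = x.size
    s = float(np.sum(np.log(x / beta)))
    r = beta / h
    log_r = math.log(r)

    def score(alpha: float) -> float:
        ra = r**alpha
        return n / alpha + n * ra * log_r / (1.0 - ra) - s

    # score is decreasing in alpha; bracket the root on a log grid
    lo, hi = 1e-8, 1.0
    while score(hi) > 0 and hi < 1e6:
        lo, hi = hi, hi * 10.0
    if score(hi) > 0:
        raise FitError("truncated Pareto shape did not bracket; data too light-tailed")
    return float(optimize.brentq(score, lo, hi, xtol=1e-12, rtol=1e-12))


def _loglik(family: str, x: np.ndarray, shape: float, scale: float, h: float | None) -> float:
    n = x.size
    a, b = shape, scale
    if family == "gamma":
        return float(np.sum(a * math.log(b) - special.gammaln(a) + (a - 1) * np.log(x) - b * x))
    if family == "lognormal":
        lx = np.log(x)
        return float(np.sum(-np.log(b * x) - 0.5 * math.log(2 * math.pi) - (lx - a) ** 2 / (2 * b**2)))
    if family == "pareto":
        return float(n * (math.log(a) + a * math.log(b)) - (a + 1) * np.sum(np.log(x)))
    if family == "truncated_pareto":
        r = b / h
        return float(
            n * (math.log(a) + a * math.log(b) - math.log1p(-(r**a))) - (a + 1) * np.sum(np.log(x))
        )
    if family == "weibull":
        return float(np.sum(stats.weibull_min.logpdf(x, a, scale=b)))
    if family == "lomax":
        return float(np.sum(stats.lomax.logpdf(x, a, scale=b)))
    raise ValueError(f"unknown family {family!r}")


def fit_distribution(
    sizes: Sequence[float] | np.ndarray,
    family: str,
    log_transform: bool = False,
) -> DistributionFit:
    """Maximum-likelihood fit of one heavy-tailed family.

    With ``log_transform=True`` the fit is performed on ln(size); this is
    only meaningful for the unbounded-support families
    (:data:`LOG_FAMILIES`), and the returned fit carries
    ``log_transformed=True`` so downstream GOF evaluation transforms the
    data consistently.
    """
    x = _check_sizes(sizes)
    if log_transform:
        if family not in LOG_FAMILIES:
            raise ValueError(f"log_transform is only supported for {LOG_FAMILIES}, not {family!r}")
        x = np.log(x)
        if np.any(x <= 0):
            raise FitError("log-transformed sizes must remain positive (sizes must exceed 1)")
    if np.ptp(x) == 0:
        raise DegeneracyError("all observations identical; no spread to fit")

    h: float | None = None
    if family == "gamma":
        shape, _, scl = stats.gamma.fit(x, floc=0)
        scale = 1.0 / scl  # report the rate, matching the pdf above
    elif family == "lognormal":
        lx = np.log(x)
        shape = float(np.mean(lx))  # log-mean
        scale = float(np.std(lx))  # log-sd, MLE (1/n) denominator
        if scale == 0:
            raise DegeneracyError("zero log-variance sample")
    elif family == "pareto":
        scale = float(np.min(x))
        s = float(np.sum(np.log(x / scale)))
        if s == 0:
            raise DegeneracyError("all observations at the sample minimum")
        shape = x.size / s  # Hill estimator
    elif family == "truncated_pareto":
        scale = float(np.min(x))
        h = float(np.max(x))
        shape = _truncated_pareto_alpha(x, scale, h)
    elif family == "weibull":
        shape, _, scale = stats.weibull_min.fit(x, floc=0)
    elif family == "lomax":
        shape, _, scale = stats.lomax.fit(x, floc=0)
    else:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")

    if not (shape > 0 and scale >= 0 and np.isfinite(shape) and np.isfinite(scale)):
        raise FitError(f"{family} fit produced invalid parameters: shape={shape}, scale={scale}")
    ll = _loglik(family, x, shape, scale, h)
    if not np.isfinite(ll):
        raise FitError(f"{family} log-likelihood not finite at the optimum")
    return DistributionFit(
        family=family,
        shape=float(shape),
        scale=float(scale),
        loglik=ll,
        n=int(x.size),
        support_min=float(np.min(x)),
        h=h,
        log_transformed=log_transform,
    )


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------


def goodness_of_fit(fit: DistributionFit, sizes: Sequence[float] | np.ndarray) -> GofReport:
    """AIC, Kolmogorov–Smirnov, and Cramér–von Mises scores for a fit.

    AIC = 2k - 2 loglik with k = 2 free parameters.  KS and CvM are the
    plain empirical statistics against the fitted CDF (no bootstrap
    calibration of estimated parameters):

        KS  = max_i max(|i/n - F(x_(i))|, |(i-1)/n - F(x_(i))|)
        CvM = 1/(12n) + sum_i ((2i-1)/(2n) - F(x_(i)))^2
    """
    x = np.sort(np.asarray(sizes, dtype=float).ravel())
    if fit.log_transformed:
        x = np.log(x)
    n = x.size
    f = fit.cdf(x)
    if not np.all(np.isfinite(f)):
        raise FitError("fitted CDF not evaluable at a data point")
    i = np.arange(1, n + 1)
    ks = float(np.max(np.maximum(np.abs(i / n - f), np.abs((i - 1) / n - f))))
    cvm = float(1.0 / (12 * n) + np.sum(((2 * i - 1) / (2 * n) - f) ** 2))
    aic = 2 * fit.k - 2 * fit.loglik
    return GofReport(aic=float(aic), ks=ks, cvm=cvm)


# ---------------------------------------------------------------------------
# Mean excess and threshold selection
# ---------------------------------------------------------------------------


def mean_excess_curve(
    sizes: Sequence[float] | np.ndarray, min_exceedances: int = 10
) -> MeanExcessCurve:
    """Mean excess e(u) evaluated at ascending sample order statistics.

    e(u) = mean(x_i - u | x_i > u).  The curve is truncated where fewer
    than ``min_exceedances`` observations remain above u, since the tail
    mean becomes too noisy to read.  A linear-in-u mean excess diagnoses a
    generalized-Pareto tail; its slope is 1/(alpha-1) for a Pareto shape
    alpha > 1.
    """
    x = np.sort(np.asarray(sizes, dtype=float).ravel())
    n = x.size
    if n < min_exceedances:
        raise FitError(f"need at least min_exceedances={min_exceedances} observations")
    # thresholds at distinct order statistics; exceedances are strict
    us, es, ns = [], [], []
    # suffix sums for O(n) evaluation
    csum = np.concatenate([np.cumsum(x[::-1])[::-1], [0.0]])
    for idx in range(n):
        u = x[idx]
        if idx > 0 and u == x[idx - 1]:
            continue
        # first index strictly greater than u
        j = int(np.searchsorted(x, u, side="right"))
        m = n - j
        if m < min_exceedances:
            break
        us.append(u)
        es.append(csum[j] / m - u)
        ns.append(m)
    if not us:
        raise FitError("no threshold retains the required number of exceedances")
    return MeanExcessCurve(
        thresholds=np.asarray(us), mean_excess=np.asarray(es), n_exceed=np.asarray(ns)
    )


#: Recommended minimum exceedance count for curves fed to threshold
#: selection: mean-excess points estimated from fewer observations are too
#: noisy to localize a change point, especially under infinite-variance
#: tails (Pareto shape <= 2).
SELECTION_MIN_EXCEEDANCES = 50


def _line_rss(u: np.ndarray, e: np.ndarray, w: np.ndarray) -> float:
    if u.size < 2 or np.ptp(u) == 0:
        return 0.0
    coef = np.polyfit(u, e, 1, w=np.sqrt(w))
    resid = e - np.polyval(coef, u)
    return float(np.sum(w * resid**2))


def select_threshold(
    curve: MeanExcessCurve, candidate_grid: Sequence[float] | np.ndarray
) -> ThresholdSelection:
    """Pick the tail threshold as the start of the linear mean-excess region.

    Two-part change-point heuristic: for each candidate u*, one straight
    line is fitted to the curve points below u* and another to the points
    at or above u*; the candidate minimizing the total weighted residual
    sum of squares wins.  Points are weighted by their exceedance count
    (an inverse-variance proxy: e(u) is a mean of n_exceed excesses), so
    the erratic high-threshold end of the curve cannot dominate; for the
    same reason, curves intended for selection should be built with
    ``min_exceedances`` of about :data:`SELECTION_MIN_EXCEEDANCES`.
    Fitting the body separately penalizes choices that discard genuinely
    linear tail points into a curved body segment.  Ties (within 1e-9
    relative) break toward the smallest candidate, so an
    everywhere-linear curve yields the smallest candidate.
    """
    u = np.asarray(curve.thresholds, dtype=float)
    e = np.asarray(curve.mean_excess, dtype=float)
    w = np.asarray(curve.n_exceed, dtype=float)
    if u.size == 0:
        raise FitError("empty mean-excess curve")
    candidates = sorted(float(c) for c in candidate_grid)
    objective: dict[float, float] = {}
    best: tuple[float, float] | None = None
    tail_fit: dict[float, tuple[float, float]] = {}
    for cand in candidates:
        above = u >= cand
        if int(above.sum()) < 3:
            continue
        rss = _line_rss(u[~above], e[~above], w[~above]) + _line_rss(u[above], e[above], w[above])
        objective[cand] = rss
        coef = np.polyfit(u[above], e[above], 1, w=np.sqrt(w[above]))
        tail_fit[cand] = (float(coef[0]), float(coef[1]))
        # a later candidate must improve by a real margin (not float noise)
        if best is None or rss < best[1] - 1e-9 * (1.0 + best[1]):
            best = (cand, rss)
    if best is None:
        raise FitError("fewer than 3 curve points above every candidate threshold")
    slope, intercept = tail_fit[best[0]]
    return ThresholdSelection(
        threshold=best[0], slope=slope, intercept=intercept, objective=objective
    )


# ---------------------------------------------------------------------------
# Family comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilyComparison:
    """Fits + GOF for several families with per-criterion rankings."""

    results: tuple[tuple[DistributionFit, GofReport], ...]
    failures: dict[str, str]
    ranking: dict[str, tuple[str, ...]]  # criterion -> families, best first

    def best(self, criterion: str = "aic") -> str:
        return self.ranking[criterion][0]


def compare_families(
    sizes: Sequence[float] | np.ndarray,
    families: Sequence[str] = FAMILIES,
    log_transform: bool = False,
) -> FamilyComparison:
    """Fit several families on identical data and rank them.

    Rankings are computed separately for AIC, KS, and CvM (smaller is
    better for all three); ties break deterministically by family name.
    A family whose fit fails is recorded in ``failures`` and excluded from
    the rankings without aborting the others.
    """
    if len(families) < 2:
        raise ValueError("need at least two families to compare")
    results: list[tuple[DistributionFit, GofReport]] = []
    failures: dict[str, str] = {}
    for fam in families:
        try:
            fit = fit_distribution(sizes, fam, log_transform=log_transform)
            results.append((fit, goodness_of_fit(fit, sizes)))
        except (FitError, ValueError) as exc:
            failures[fam] = str(exc)
    if not results:
        raise FitError(f"all families failed: {failures}")
    ranking = {
        crit: tuple(
            fit.family
            for fit, gof in sorted(results, key=lambda fr: (getattr(fr[1], crit), fr[0].family))
        )
        for crit in ("aic", "ks", "cvm")
    }
    return FamilyComparison(results=tuple(results), failures=failures, ranking=ranking)
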