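"""Multivariate ignition-risk analysis on gridded covariates.

Pipeline order: a Pearson correlation screen over co-registered covariate
rasters drops one variable from each highly correlated pair (|r| > 0.5 by
default); PCA summarizes the interrelation of the remaining variables;
the study window is divided into square analysis cells (3 km by default),
each flagged 1 if any ignition point falls in it; and a binomial logistic
regression

    ln(P / (1 - P)) = w0 + w1 x1 + ... + wn xn

relates the presence flag to the cell-averaged covariates, with Wald
standard errors and two-sided p-values per coefficient.  No spatial
autocorrelation correction is applied: cells are treated as independent
observations, which overstates precision where ignitions cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .catalog import FireCatalog
from .density import RasterGrid

__all__ = [
    "TABLE_VARIABLES",
    "CovariateStack",
    "CorrelationMatrix",
    "RemovalResult",
    "PCAResult",
    "GridDataset",
    "LogisticFit",
    "raster_correlation",
    "filter_correlated",
    "pca",
    "grid_aggregate",
    "logistic_fit",
]

logger = logging.getLogger(__name__)

#: The standard covariate roster: human, terrain, fuel, and climate variables.
TABLE_VARIABLES = (
    "distance_to_roads",
    "distance_to_powerline",
    "housing_density",
    "population_density",
    "elevation",
    "slope",
    "aspect",
    "tree",
    "shrub",
    "grass",
    "tmax",
    "vpdmax",
)


@dataclass
class CovariateStack:
    """Named covariate rasters sharing one georeference."""

    layers: dict[str, RasterGrid]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("empty covariate stack")
        ref = next(iter(self.layers.values()))
        for name, layer in self.layers.items():
            if not layer.same_georef(ref):
                raise ValueError(f"layer {name!r} does not share the stack georeference")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.layers)

    @property
    def reference(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def to_frame(self) -> pd.DataFrame:
        """One row per cell jointly valid in every layer."""
        mask = np.ones(self.reference.values.shape, dtype=bool)
        for layer in self.layers.values():
            mask &= layer.mask()
        return pd.DataFrame({name: layer.values[mask] for name, layer in self.layers.items()})


@dataclass(frozen=True)
class CorrelationMatrix:
    names: tuple[str, ...]
    r: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=list(self.names), columns=list(self.names))


def raster_correlation(
    stack: CovariateStack, mask: np.ndarray | None = None
) -> CorrelationMatrix:
    """Pairwise Pearson correlation of stack layers over valid cells.

    Uses the N-1 (sample) covariance.  ``mask`` optionally restricts the
    cells entering the computation (e.g. to burned perimeters).
    """
    valid = np.ones(stack.reference.values.shape, dtype=bool)
    for layer in stack.layers.values():
        valid &= layer.mask()
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    n = int(valid.sum())
    if len(stack.layers) < 2:
        raise ValueError("need at least two layers")
    if n < 3:
        raise ValueError(f"need at least 3 unmasked cells, got {n}")
    data = np.stack([layer.values[valid] for layer in stack.layers.values()])
    sd = data.std(axis=1, ddof=1)
    for name, s in zip(stack.names, sd):
        if s == 0:
            raise ValueError(f"layer {name!r} has zero variance over the unmasked cells")
    r = np.corrcoef(data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)  # enforce exact symmetry
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(names=stack.names, r=r)


@dataclass(frozen=True)
class RemovalResult:
    retained: tuple[str, ...]
    removed: tuple[str, ...]
    log: tuple[str, ...]


def filter_correlated(
    matrix: CorrelationMatrix,
    threshold: float = 0.5,
    keep_rules: Sequence[str] | None = None,
) -> RemovalResult:
    """Greedy screen: drop variables until no pair has |r| > threshold.

    At each step the variables involved in at least one violating pair are
    candidates for removal; the one with the largest mean |r| to the other
    retained variables is dropped.  ``keep_rules`` lists variables to
    prefer keeping: a protected variable is only dropped if every
    candidate is protected.  The procedure is deterministic (ties break
    alphabetically) and returns a removal log.
    """
    keep = set(keep_rules or ())
    names = list(matrix.names)
    r = np.abs(matrix.r.copy())
    np.fill_diagonal(r, 0.0)
    retained = list(names)
    removed: list[str] = []
    log: list[str] = []
    while True:
        idx = [names.index(v) for v in retained]
        sub = r[np.ix_(idx, idx)]
        violating = {retained[i] for i, j in zip(*np.where(sub > threshold))}
        if not violating:
            break
        candidates = sorted(violating - keep) or sorted(violating)
        mean_r = {
            v: sub[retained.index(v)].sum() / (len(retained) - 1) for v in candidates
        }
        drop = max(candidates, key=lambda v: (mean_r[v], [-ord(c) for c in v]))
        partners = sorted(
            u for u in violating if u != drop and sub[retained.index(u), retained.index(drop)] > threshold
        )
        log.append(f"removed {drop} (mean |r| {mean_r[drop]:.3f}; conflicts with {partners})")
        retained.remove(drop)
        removed.append(drop)
    return RemovalResult(retained=tuple(retained), removed=tuple(removed), log=tuple(log))


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray  # descending
    loadings: pd.DataFrame  # variables x components, orthonormal columns
    explained: np.ndarray  # variance fractions
    cumulative: np.ndarray


def pca(table, standardize: bool = True) -> PCAResult:
    """Principal component analysis by eigendecomposition.

    ``table`` may be a DataFrame (rows = observations), a
    :class:`CovariateStack`, or a :class:`GridDataset`.  With
    ``standardize=True`` (default) the correlation matrix is decomposed,
    which puts incommensurate units (degrees, percent, hPa) on one scale;
    otherwise the raw covariance matrix is used.  The sign convention
    makes the largest-magnitude loading of each component positive.
    """
    if isinstance(table, CovariateStack):
        frame = table.to_frame()
    elif isinstance(table, GridDataset):
        frame = table.table[list(table.covariate_names)]
    else:
        frame = pd.DataFrame(table)
    X = frame.to_numpy(dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least two variables")
    if n <= k:
        raise ValueError(f"need more observations ({n}) than variables ({k})")
    C = np.corrcoef(X, rowvar=False) if standardize else np.cov(X, rowvar=False)
    if not np.all(np.isfinite(C)):
        raise ValueError("covariance matrix not finite (constant column?)")
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    if eigval[-1] <= 1e-12 * eigval[0]:
        logger.warning("rank-deficient input: smallest eigenvalue ~ 0")
    flip = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(k)])
    eigvec = eigvec * np.where(flip == 0, 1.0, flip)
    explained = eigval / eigval.sum()
    loadings = pd.DataFrame(
        eigvec, index=frame.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PCAResult(
        eigenvalues=eigval,
        loadings=loadings,
        explained=explained,
        cumulative=np.cumsum(explained),
    )


@dataclass
class GridDataset:
    """Square analysis cells with a binary ignition-presence flag and
    cell-averaged covariates (the logistic design matrix)."""

    table: pd.DataFrame  # cell_id, cx, cy, presence, <covariates...>
    cell_size: float
    origin: tuple[float, float]  # lower-left corner of the cell lattice
    n_points_outside: int = 0

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.table.columns if c not in ("cell_id", "cx", "cy", "presence"))


def grid_aggregate(
    catalog: FireCatalog,
    stack: CovariateStack,
    cell_size: float = 3000.0,
    window: tuple[float, float, float, float] | None = None,
) -> GridDataset:
    """Build the presence/covariate dataset on square analysis cells.

    Cells are half-open intervals [x, x+cell_size) x [y, y+cell_size)
    anchored at the window's lower-left corner, so every point belongs to
    exactly one cell.  A cell's presence flag is 1 iff at least one
    ignition point falls in it; its covariates are the means of the stack
    cells whose centers fall in it.  Cells containing no valid stack cell
    are dropped; catalog points outside the window are counted in
    ``n_points_outside`` and excluded.
    """
    ref = stack.reference
    if window is None:
        window = (ref.x0, ref.y0 - ref.n_rows * ref.cell_size, ref.x0 + ref.n_cols * ref.cell_size, ref.y0)
    xmin, ymin, xmax, ymax = window
    n_cx = int(np.ceil((xmax - xmin) / cell_size))
    n_cy = int(np.ceil((ymax - ymin) / cell_size))

    cx, cy = ref.cell_centers()
    valid = np.ones(ref.values.shape, dtype=bool)
    for layer in stack.layers.values():
        valid &= layer.mask()
    inside = (cx >= xmin) & (cx < xmax) & (cy >= ymin) & (cy < ymax) & valid
    col = np.floor((cx[inside] - xmin) / cell_size).astype(int)
    row = np.floor((cy[inside] - ymin) / cell_size).astype(int)
    cell_id = row * n_cx + col

    agg = pd.DataFrame({"cell_id": cell_id})
    for name, layer in stack.layers.items():
        agg[name] = layer.values[inside]
    means = agg.groupby("cell_id").mean()

    presence = pd.Series(0, index=means.index, dtype=int)
    outside = 0
    for rec in catalog:
        if not (xmin <= rec.x < xmax and ymin <= rec.y < ymax):
            outside += 1
            continue
        cid = int((rec.y - ymin) // cell_size) * n_cx + int((rec.x - xmin) // cell_size)
        if cid in presence.index:
            presence.loc[cid] = 1
    if outside:
        logger.warning("%d catalog points fall outside the analysis window", outside)

    table = means.reset_index()
    table.insert(1, "cx", xmin + (table["cell_id"] % n_cx + 0.5) * cell_size)
    table.insert(2, "cy", ymin + (table["cell_id"] // n_cx + 0.5) * cell_size)
    table.insert(3, "presence", presence.values)
    return GridDataset(
        table=table, cell_size=cell_size, origin=(xmin, ymin), n_points_outside=outside
    )


@dataclass(frozen=True)
class LogisticFit:
    """Logistic regression coefficients with Wald inference."""

    coefficients: pd.Series  # includes "intercept"
    std_errors: pd.Series
    p_values: pd.Series
    converged: bool
    separation: bool
    n: int
    loglik: float


def logistic_fit(grid: GridDataset, variables: Sequence[str] | None = None) -> LogisticFit:
    """Fit the ignition-presence logistic model by maximum likelihood.

    Uses iteratively reweighted least squares (Newton scoring); reports
    Wald standard errors and two-sided p-values.  Complete or
    quasi-complete separation is reported on the result rather than
    silently swallowed.
    """
    variables = list(variables if variables is not None else grid.covariate_names)
    missing = [v for v in variables if v not in grid.table.columns]
    if missing:
        raise ValueError(f"variables not in the grid dataset: {missing}")
    y = grid.table["presence"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("presence response has a single class; cannot fit")
    X = sm.add_constant(grid.table[variables].to_numpy(dtype=float)) if variables else np.ones((y.size, 1))
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates contain non-finite values")

    names = ["intercept"] + variables
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:
            # a singular Hessian under Newton scoring is the classic
            # footprint of (quasi-)complete separation: report it and fall
            # back to a faintly ridge-penalized fit for point estimates
            if "singular" not in str(exc).lower() and "separation" not in str(exc).lower():
                raise RuntimeError(f"logistic fit failed: {exc}") from exc
            logger.warning("separation detected in logistic fit: %s", exc)
            res = sm.Logit(y, X).fit_regularized(alpha=1e-6, L1_wt=0.0, disp=0)
            return LogisticFit(
                coefficients=pd.Series(np.asarray(res.params), index=names),
                std_errors=pd.Series(np.inf, index=names),
                p_values=pd.Series(np.nan, index=names),
                converged=False,
                separation=True,
                n=int(y.size),
                loglik=float(res.llf),
            )
        for w in caught:
            if "separation" in str(w.message).lower():
                separation = True
                logger.warning("separation detected in logistic fit: %s", w.message)

    return LogisticFit(
        coefficients=pd.Series(res.params, index=names),
        std_errors=pd.Series(res.bse, index=names),
        p_values=pd.Series(res.pvalues, index=names),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation,
        n=int(y.size),
        loglik=float(res.llf),
    )
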