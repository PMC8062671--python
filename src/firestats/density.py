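"""Weighted kernel density surfaces for ignition points, on a raster grid.

The estimator is the quartic (biweight) kernel with a hard search radius R:

    f(x) = (1/R^2) * sum_i (3/pi) * P_i * (1 - (d_i/R)^2)^2,   d_i < R

where d_i is the planar distance from grid location x to point i and P_i
is the point's weight ("population field"): 1 for occurrence density, the
burned area for area-weighted density.  The kernel reaches exactly zero at
the search radius, so every cell farther than R from all points is exactly
zero.  With this normalization each point contributes total mass P_i, so
the surface integrates to the total weight (checked by the test suite via
numeric quadrature), and densities are per square meter.

Rasters use a top-left origin with row-major addressing: cell (r, c) has
center (x0 + (c + 0.5) * cell_size, y0 - (r + 0.5) * cell_size).  I/O is
the ESRI ASCII grid format, which stores rows top to bottom and anchors
the grid at its lower-left corner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .catalog import EmptyCatalogError, FireCatalog

__all__ = [
    "RasterGrid",
    "KDEParams",
    "ClassifiedRaster",
    "DegenerateGeometryError",
    "kernel_density",
    "default_search_radius",
    "classify_density",
    "read_ascii_grid",
    "write_ascii_grid",
]

NODATA = -9999.0


class DegenerateGeometryError(ValueError):
    """Point geometry with no spread where spread is required."""


@dataclass
class RasterGrid:
    """Georeferenced cell lattice (top-left origin, row-major values)."""

    x0: float  # west edge
    y0: float  # north edge
    cell_size: float
    values: np.ndarray  # shape (n_rows, n_cols)
    nodata: float = NODATA

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(cx, cy) arrays of shape (n_rows, n_cols)."""
        cs = self.cell_size
        cx = self.x0 + (np.arange(self.n_cols) + 0.5) * cs
        cy = self.y0 - (np.arange(self.n_rows) + 0.5) * cs
        return np.meshgrid(cx, cy)

    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata, finite) cells."""
        return np.isfinite(self.values) & (self.values != self.nodata)

    def same_georef(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.x0, other.x0)
            and math.isclose(self.y0, other.y0)
            and math.isclose(self.cell_size, other.cell_size)
        )


@dataclass(frozen=True)
class KDEParams:
    """Search radius, output resolution, and weighting mode for the KDE."""

    search_radius: float  # meters
    cell_size: float = 500.0  # meters
    weight_mode: str = "unit"  # or "burned_area"

    def __post_init__(self) -> None:
        if self.weight_mode not in ("unit", "burned_area"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if not self.search_radius > self.cell_size:
            raise ValueError("search_radius must exceed cell_size")


def _points_and_weights(catalog: FireCatalog, params: KDEParams):
    if len(catalog) == 0:
        raise EmptyCatalogError("KDE needs at least one point")
    px = np.array([r.x for r in catalog])
    py = np.array([r.y for r in catalog])
    if params.weight_mode == "burned_area":
        w = np.array([r.size_acres for r in catalog])
        if np.any(w <= 0):
            raise ValueError("burned-area weights must be strictly positive")
    else:
        w = np.ones(len(catalog))
    return px, py, w


def kernel_density(catalog: FireCatalog, params: KDEParams) -> RasterGrid:
    """Quartic-kernel density surface over the catalog's ignition points.

    The raster extent is the point bounding box padded by the search
    radius (snapped outward to whole cells), so no kernel is clipped; no
    edge correction is applied.  Cell values are weight per square meter.
    """
    px, py, w = _points_and_weights(catalog, params)
    R, cs = params.search_radius, params.cell_size

    x0 = math.floor((px.min() - R) / cs) * cs
    y0 = math.ceil((py.max() + R) / cs) * cs
    n_cols = max(1, math.ceil((px.max() + R - x0) / cs))
    n_rows = max(1, math.ceil((y0 - (py.min() - R)) / cs))
    values = np.zeros((n_rows, n_cols))

    cx = x0 + (np.arange(n_cols) + 0.5) * cs
    cy = y0 - (np.arange(n_rows) + 0.5) * cs
    norm = 3.0 / (math.pi * R * R)
    span = int(math.ceil(R / cs)) + 1
    for xi, yi, wi in zip(px, py, w):
        c0 = int((xi - x0) // cs)
        r0 = int((y0 - yi) // cs)
        cl, ch = max(0, c0 - span), min(n_cols, c0 + span + 1)
        rl, rh = max(0, r0 - span), min(n_rows, r0 + span + 1)
        dx = cx[cl:ch] - xi
        dy = cy[rl:rh] - yi
        d2 = (dy[:, None] ** 2 + dx[None, :] ** 2) / (R * R)
        inside = d2 < 1.0
        contrib = np.where(inside, wi * norm * (1.0 - d2) ** 2, 0.0)
        values[rl:rh, cl:ch] += contrib
    return RasterGrid(x0=x0, y0=y0, cell_size=cs, values=values)


def default_search_radius(
    catalog: FireCatalog, weights: Sequence[float] | np.ndarray | None = None
) -> float:
    """Rule-of-thumb search radius from the spread of the weighted points.

    R = 0.9 * min(SD, sqrt(1/ln 2) * Dm) * n_eff^(-1/5)

    where SD is the weighted standard distance from the weighted mean
    center, Dm the weighted median distance to that center, and
    n_eff = (sum w)^2 / sum w^2 the effective number of points (equal to n
    for equal weights).  The formula is scale-equivariant: scaling all
    coordinates by s scales R by s.  It is a smoothing default, not an
    inference; analyses that matter should pin R explicitly.
    """
    if len(catalog) < 2:
        raise EmptyCatalogError("need at least two points for a default radius")
    px = np.array([r.x for r in catalog])
    py = np.array([r.y for r in catalog])
    w = np.ones(len(catalog)) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != px.shape or np.any(w <= 0):
        raise ValueError("weights must be positive, one per point")
    wsum = w.sum()
    mx, my = (w * px).sum() / wsum, (w * py).sum() / wsum
    d2 = (px - mx) ** 2 + (py - my) ** 2
    sd = math.sqrt((w * d2).sum() / wsum)
    if sd == 0:
        raise DegenerateGeometryError("all points coincident; no spread to derive a radius from")
    order = np.argsort(np.sqrt(d2))
    cum = np.cumsum(w[order])
    dm = float(np.sqrt(d2)[order][np.searchsorted(cum, 0.5 * wsum)])
    n_eff = wsum**2 / (w**2).sum()
    return 0.9 * min(sd, math.sqrt(1.0 / math.log(2.0)) * dm) * n_eff ** (-0.2)


@dataclass(frozen=True)
class ClassifiedRaster:
    """Ordinal density classes (1..n, low to high); 0 marks nodata/zero cells."""

    grid: RasterGrid
    boundaries: np.ndarray  # interior quantile boundaries, length n_classes - 1


def classify_density(raster: RasterGrid, n_classes: int = 5) -> ClassifiedRaster:
    """Quantile classification of the nonzero cells into ordinal classes.

    Class c covers the (c-1)/n .. c/n quantile band of the nonzero density
    values, so class maps are invariant under any strictly increasing
    transform of the densities.  Zero and nodata cells stay unclassified
    (value 0).
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    vals = raster.values
    live = raster.mask() & (vals > 0)
    nz = vals[live]
    if np.unique(nz).size < n_classes:
        raise ValueError(
            f"only {np.unique(nz).size} distinct nonzero values; cannot form {n_classes} classes"
        )
    boundaries = np.quantile(nz, np.arange(1, n_classes) / n_classes)
    classes = np.zeros(vals.shape, dtype=float)
    classes[live] = 1 + np.searchsorted(boundaries, nz, side="left")
    classes[live] = np.minimum(classes[live], n_classes)
    out = RasterGrid(
        x0=raster.x0, y0=raster.y0, cell_size=raster.cell_size, values=classes, nodata=0.0
    )
    return ClassifiedRaster(grid=out, boundaries=boundaries)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------


def write_ascii_grid(raster: RasterGrid, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (rows top to bottom)."""
    path = Path(path)
    yll = raster.y0 - raster.n_rows * raster.cell_size
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {raster.x0!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        for row in raster.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    with path.open() as fh:
        head = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            key, _, val = fh.readline().partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                head[key] = float(val)
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    n_rows, n_cols = int(head["nrows"]), int(head["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"grid body shape {values.shape} disagrees with header ({n_rows}, {n_cols})")
    cs = head["cellsize"]
    return RasterGrid(
        x0=head["xllcorner"],
        y0=head["yllcorner"] + n_rows * cs,
        cell_size=cs,
        values=values,
        nodata=head.get("nodata_value", NODATA),
    )
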