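"""Seeded generators for fire catalogs, covariate stacks, and presence grids.

Every generator is a pure function of its :class:`SyntheticConfig` (seed
included): the same config yields the same bytes.  Per-component
sub-generators are seeded at fixed offsets from the config seed, so adding
a new generator never perturbs the output of the existing ones.

Size laws are sampled by inverse-CDF transforms of the same
parameterizations the fitting module uses, plus a spliced law — a
lognormal body truncated to [min_size, threshold) grafted onto a Pareto
tail above the threshold — which reproduces the characteristic
mean-excess signature of real burned-area data: curved below the splice
point, linear above it.

Covariate rasters are smooth Gaussian random fields (white noise smoothed
to a requested correlation length).  Requested cross-correlations between
layers are achieved *exactly* in the empirical sample: the base fields are
empirically whitened and then mixed through the Cholesky factor of the
target correlation matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import special, stats
from scipy.ndimage import gaussian_filter

from .catalog import CAUSE_GROUPS, DB_MIN_SIZE_ACRES, FireCatalog, FireRecord, cause_vocabulary
from .covariates import CovariateStack, GridDataset, grid_aggregate
from .density import RasterGrid

__all__ = [
    "SyntheticConfig",
    "ConfigError",
    "gen_catalog",
    "gen_covariate_stack",
    "gen_presence_grid",
    "sample_sizes",
    "california_like",
]

# Fixed sub-seed offsets per component (documented contract: stable forever).
_OFF_SIZES = 1
_OFF_YEARS = 2
_OFF_MONTHS = 3
_OFF_CAUSES = 4
_OFF_LOCS = 5
_OFF_FUEL = 6
_OFF_FIELDS = 7
_OFF_PRESENCE = 8


class ConfigError(ValueError):
    """Invalid generative configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative description of a synthetic study scenario."""

    n_fires: int
    period: tuple[int, int]
    size_law: Mapping  # {"family": str, "params": {...}}
    cause_mix: Mapping[str, float]
    month_weights: Sequence[float]
    window: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    hotspots: Sequence[Mapping]  # cx, cy, sd, weight
    covariate_fields: Mapping[str, Mapping] = field(default_factory=dict)
    cross_correlation: Sequence = ()
    logistic_coefficients: Mapping[str, float] = field(default_factory=dict)
    stack_cell_size: float = 3000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fires < 0:
            raise ConfigError("n_fires must be >= 0")
        for name, probs in (
            ("cause_mix", list(self.cause_mix.values())),
            ("month_weights", list(self.month_weights)),
            ("hotspot weights", [h["weight"] for h in self.hotspots]),
        ):
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-6:
                raise ConfigError(f"{name} must be nonnegative and sum to 1")
        if len(self.month_weights) != 12:
            raise ConfigError("month_weights must have 12 entries")
        if set(self.cause_mix) - set(CAUSE_GROUPS):
            raise ConfigError(f"unknown cause groups: {set(self.cause_mix) - set(CAUSE_GROUPS)}")
        for h in self.hotspots:
            if not h["sd"] > 0:
                raise ConfigError("hotspot sd must be positive")

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(source).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SyntheticConfig":
        return cls(
            n_fires=int(raw["n_fires"]),
            period=tuple(raw["period"]),
            size_law=raw["size_law"],
            cause_mix=dict(raw["cause_mix"]),
            month_weights=list(raw["month_weights"]),
            window=tuple(raw["window"]),
            hotspots=list(raw["hotspots"]),
            covariate_fields=dict(raw.get("covariate_fields", {})),
            cross_correlation=[tuple(t) for t in raw.get("cross_correlation", [])],
            logistic_coefficients=dict(raw.get("logistic_coefficients", {})),
            stack_cell_size=float(raw.get("stack_cell_size", 3000.0)),
            seed=int(raw.get("seed", 0)),
        )


def california_like(seed: int | None = None) -> SyntheticConfig:
    """The canonical packaged scenario; ``seed`` optionally overrides."""
    text = resources.files("firestats.data").joinpath("california_like.yaml").read_text()
    cfg = SyntheticConfig.from_dict(yaml.safe_load(text))
    return replace(cfg, seed=seed) if seed is not None else cfg


# ---------------------------------------------------------------------------
# Size sampling (inverse CDF)
# ---------------------------------------------------------------------------


def sample_sizes(family: str, params: Mapping[str, float], n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` burned areas from a size law, by inverse-CDF transforms."""
    p = dict(params)
    if family == "pareto":
        u = rng.random(n)
        return p["beta"] * (1.0 - u) ** (-1.0 / p["alpha"])
    if family == "truncated_pareto":
        u = rng.random(n)
        r = (p["beta"] / p["h"]) ** p["alpha"]
        return p["beta"] * (1.0 - u * (1.0 - r)) ** (-1.0 / p["alpha"])
    if family == "lognormal":
        return np.exp(p["alpha"] + p["beta"] * rng.standard_normal(n))
    if family == "gamma":
        return rng.gamma(p["alpha"], 1.0 / p["beta"], n)  # beta is a rate
    if family == "weibull":
        return p["beta"] * rng.weibull(p["alpha"], n)
    if family == "spliced_lognormal_pareto":
        m, s = p["body_logmean"], p["body_logsd"]
        a = (math.log(p["min_size"]) - m) / s
        b = (math.log(p["threshold"]) - m) / s
        tail = rng.random(n) < p["p_tail"]
        out = np.empty(n)
        u = rng.random(n)
        out[~tail] = np.exp(stats.truncnorm.ppf(u[~tail], a, b, loc=m, scale=s))
        out[tail] = p["threshold"] * (1.0 - u[tail]) ** (-1.0 / p["tail_alpha"])
        return out
    raise ConfigError(f"unknown size-law family {family!r}")


# ---------------------------------------------------------------------------
# Catalog generation
# ---------------------------------------------------------------------------


def _rng(config: SyntheticConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng(int(config.seed) + offset)


def gen_catalog(config: SyntheticConfig) -> FireCatalog:
    """Generate a fire catalog with the configured statistical structure.

    Sizes are i.i.d. from the size law; discovery years are uniform over
    the period and months multinomial on the month weights; cause groups
    follow the cause mix, with the raw code drawn uniformly within the
    group; locations come from the Gaussian-mixture hot-spot intensity.
    Fuel types are drawn among those whose database minimum size the fire
    meets, so generated catalogs satisfy the fuel-dependent inclusion rule
    by construction.
    """
    n = config.n_fires
    if n == 0:
        return FireCatalog(records=(), period=None)
    sizes = sample_sizes(config.size_law["family"], config.size_law["params"], n, _rng(config, _OFF_SIZES))
    years = _rng(config, _OFF_YEARS).integers(config.period[0], config.period[1] + 1, n)
    months = 1 + _rng(config, _OFF_MONTHS).choice(12, n, p=np.asarray(config.month_weights, dtype=float))

    groups = list(config.cause_mix)
    probs = np.asarray([config.cause_mix[g] for g in groups], dtype=float)
    probs = probs / probs.sum()
    cause_rng = _rng(config, _OFF_CAUSES)
    group_idx = cause_rng.choice(len(groups), n, p=probs)
    by_group: dict[str, list[str]] = {}
    for code, grp in cause_vocabulary().items():
        by_group.setdefault(grp, []).append(code)
    codes = [
        by_group[groups[gi]][cause_rng.integers(len(by_group[groups[gi]]))] for gi in group_idx
    ]

    loc_rng = _rng(config, _OFF_LOCS)
    weights = np.asarray([h["weight"] for h in config.hotspots], dtype=float)
    comp = loc_rng.choice(len(config.hotspots), n, p=weights / weights.sum())
    xs = np.empty(n)
    ys = np.empty(n)
    for i, ci in enumerate(comp):
        h = config.hotspots[ci]
        xs[i] = h["cx"] + h["sd"] * loc_rng.standard_normal()
        ys[i] = h["cy"] + h["sd"] * loc_rng.standard_normal()

    fuel_rng = _rng(config, _OFF_FUEL)
    base_w = {"timber": 0.5, "brush": 0.35, "grass": 0.15}
    fuels = []
    for s in sizes:
        eligible = [f for f, mn in DB_MIN_SIZE_ACRES.items() if s >= mn]
        if not eligible:
            fuels.append(None)
            continue
        w = np.asarray([base_w[f] for f in eligible])
        fuels.append(eligible[fuel_rng.choice(len(eligible), p=w / w.sum())])

    records = tuple(
        FireRecord(
            id=f"F{i:06d}",
            x=float(xs[i]),
            y=float(ys[i]),
            year=int(years[i]),
            month=int(months[i]),
            size_acres=float(sizes[i]),
            cause=codes[i],
            fuel=fuels[i],
        )
        for i in range(n)
    )
    return FireCatalog.from_records(records, crs_note="synthetic planar CRS (meters)", period=config.period)


# ---------------------------------------------------------------------------
# Covariate stack generation
# ---------------------------------------------------------------------------


def gen_covariate_stack(config: SyntheticConfig) -> CovariateStack:
    """Smooth Gaussian random fields per covariate, with exact empirical
    means, standard deviations, and requested cross-correlations."""
    if not config.covariate_fields:
        raise ConfigError("no covariate fields configured")
    xmin, ymin, xmax, ymax = config.window
    cs = config.stack_cell_size
    n_cols = int(round((xmax - xmin) / cs))
    n_rows = int(round((ymax - ymin) / cs))
    rng = _rng(config, _OFF_FIELDS)

    names = list(config.covariate_fields)
    varying = [n for n in names if config.covariate_fields[n].get("sd", 0) > 0]
    k = len(varying)

    # target correlation matrix across varying fields
    C = np.eye(k)
    for a, b, r in config.cross_correlation:
        if a in varying and b in varying:
            i, j = varying.index(a), varying.index(b)
            C[i, j] = C[j, i] = float(r)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        raise ConfigError("cross-correlation specification is not positive definite") from None

    # base fields: white noise smoothed to the requested correlation length
    base = np.empty((n_rows * n_cols, k))
    for j, name in enumerate(varying):
        sigma = config.covariate_fields[name]["corr_length"] / cs
        fld = gaussian_filter(rng.standard_normal((n_rows, n_cols)), sigma=sigma, mode="wrap")
        base[:, j] = fld.ravel()
    # empirical whitening, then mixing: sample correlation becomes exactly C
    base -= base.mean(axis=0)
    cov = np.cov(base, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    A = np.linalg.cholesky(cov)
    mixed = base @ np.linalg.inv(A).T @ L.T

    layers: dict[str, RasterGrid] = {}
    for name in names:
        spec = config.covariate_fields[name]
        mean, sd = float(spec["mean"]), float(spec.get("sd", 0))
        if sd > 0:
            col = mixed[:, varying.index(name)]
            vals = mean + sd * (col / col.std(ddof=1))
        else:
            vals = np.full(n_rows * n_cols, mean)
        layers[name] = RasterGrid(x0=xmin, y0=ymax, cell_size=cs, values=vals.reshape(n_rows, n_cols))
    return CovariateStack(layers=layers)


# ---------------------------------------------------------------------------
# Presence grid generation
# ---------------------------------------------------------------------------


def gen_presence_grid(
    stack: CovariateStack,
    coefficients: Mapping[str, float],
    cell_size: float = 3000.0,
    seed: int = 0,
) -> GridDataset:
    """Bernoulli ignition-presence grid driven by the logistic model.

    Covariates are first averaged onto square analysis cells; each cell's
    presence probability is the inverse-logit of the linear predictor, and
    its flag is one Bernoulli draw.  ``coefficients`` maps layer names to
    weights and may include an ``"intercept"`` entry.
    """
    extra = set(coefficients) - set(stack.names) - {"intercept"}
    if extra:
        raise ConfigError(f"coefficients name unknown layers: {sorted(extra)}")
    grid = grid_aggregate(FireCatalog(records=()), stack, cell_size=cell_size)
    eta = np.full(len(grid.table), float(coefficients.get("intercept", 0.0)))
    for name, w in coefficients.items():
        if name != "intercept":
            eta += float(w) * grid.table[name].to_numpy()
    p = special.expit(eta)
    rng = np.random.default_rng(int(seed) + _OFF_PRESENCE)
    grid.table["presence"] = (rng.random(p.size) < p).astype(int)
    return grid
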