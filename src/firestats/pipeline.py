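"""End-to-end orchestration: catalog -> size fits -> threshold -> trends ->
density maps -> correlation screen -> PCA -> logistic ignition model.

Every stage writes plain tabular or raster files into the output
directory, plus a run manifest recording the configuration, the seed, the
package version, and per-stage row counts, so a run can be reproduced
bit-identically from the manifest alone.  A stage failure halts the run
with a stage-named error; outputs of completed stages are preserved.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__
from .catalog import filter_catalog, read_catalog, summarize_causes, write_catalog
from .covariates import (
    CovariateStack,
    filter_correlated,
    grid_aggregate,
    logistic_fit,
    pca,
    raster_correlation,
)
from .density import KDEParams, default_search_radius, kernel_density, write_ascii_grid
from .sizedist import (
    SELECTION_MIN_EXCEEDANCES,
    compare_families,
    mean_excess_curve,
    select_threshold,
)
from .synthetic import SyntheticConfig, california_like, gen_catalog, gen_covariate_stack
from .trends import GROUPS, annual_series, monthly_profile, peak_month, segmented_regression

__all__ = ["PipelineConfig", "ReportBundle", "StageError", "run_pipeline"]

logger = logging.getLogger(__name__)

#: Variables preferred by the correlation screen when a pair conflicts:
#: road distance over powerline distance, housing over population, and the
#: climate pair over elevation.
DEFAULT_KEEP_RULES = ("distance_to_roads", "housing_density", "tmax", "vpdmax")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline settings; the defaults are the study's standard ones
    (1920–1999 vs 2000–2019 split, 500-acre size threshold, breakpoint at
    2000, 500 m density resolution, |r| > 0.5 screen, 3 km cells)."""

    out_dir: str | Path = "firestats-output"
    scenario: str | Path | None = None  # YAML scenario; None = packaged default
    catalog_path: str | Path | None = None  # real catalog instead of a scenario
    seed: int = 0
    period_splits: tuple[tuple[int, int], ...] = ((1920, 1999), (2000, 2019))
    size_threshold: float = 500.0
    breakpoint: int = 2000
    min_fit_size: float = 10.0  # database inclusion floor, acres
    kde_cell_size: float = 500.0
    kde_search_radius: float | None = None  # None = rule-of-thumb default
    correlation_threshold: float = 0.5
    keep_rules: tuple[str, ...] = DEFAULT_KEEP_RULES
    grid_cell_size: float = 3000.0
    threshold_grid: tuple[float, ...] = tuple(float(u) for u in range(100, 2001, 50))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        d["scenario"] = None if d["scenario"] is None else str(d["scenario"])
        d["catalog_path"] = None if d["catalog_path"] is None else str(d["catalog_path"])
        return d


@dataclass
class ReportBundle:
    out_dir: Path
    manifest: dict
    tables: dict[str, Path] = field(default_factory=dict)
    rasters: dict[str, Path] = field(default_factory=dict)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=_json_default))


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full analysis and write its report bundle.

    Stage order: load/simulate inputs, cause summary, per-period size
    distribution comparison, mean-excess threshold selection, temporal
    trends and seasonality, kernel density maps (unit and burned-area
    weighted, cause-stratified), covariate correlation screen, PCA, and
    the gridded logistic ignition model.  Strata or stages that are
    impossible on the given inputs (no human-caused fires, no covariates)
    are skipped with an explicit note in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out, manifest={})
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "firestats_version": __version__,
        "stages": {},
        "skips": [],
    }
    t0 = time.perf_counter()

    def stage(name):
        logger.info("stage %s ...", name)

        def record(**info):
            manifest["stages"][name] = info
            logger.info("stage %s done (%.2fs elapsed)", name, time.perf_counter() - t0)

        return record

    # -- load ---------------------------------------------------------------
    done = stage("load")
    try:
        stack: CovariateStack | None = None
        if config.catalog_path is not None:
            catalog = read_catalog(config.catalog_path)
        else:
            scen = (
                SyntheticConfig.from_yaml(config.scenario)
                if config.scenario is not None
                else california_like()
            )
            scen = dataclasses.replace(scen, seed=config.seed)
            catalog = gen_catalog(scen)
            if scen.covariate_fields:
                stack = gen_covariate_stack(scen)
        write_catalog(catalog, out / "catalog.csv")
        bundle.tables["catalog"] = out / "catalog.csv"
        done(n_records=len(catalog), period=list(catalog.period) if catalog.period else None)
    except Exception as exc:
        raise StageError("load", exc) from exc

    # -- cause summary ------------------------------------------------------
    done = stage("cause_summary")
    try:
        summary = summarize_causes(catalog)
        path = out / "cause_summary.csv"
        summary.to_dataframe().to_csv(path, index=False)
        bundle.tables["cause_summary"] = path
        done(n_groups=len(summary.counts), total=summary.total)
    except Exception as exc:
        raise StageError("cause_summary", exc) from exc

    # -- size distributions per period --------------------------------------
    done = stage("size_distributions")
    try:
        rows = []
        fitted_periods = []
        for lo, hi in config.period_splits:
            sub = filter_catalog(catalog, period=(lo, hi))
            sizes = sub.sizes[sub.sizes >= config.min_fit_size].to_numpy()
            if sizes.size < 10:
                manifest["skips"].append(
                    f"size_distributions: period {lo}-{hi} has {sizes.size} fires >= "
                    f"{config.min_fit_size} acres; skipped"
                )
                continue
            cmp = compare_families(sizes)
            for fit, gof in cmp.results:
                rows.append(
                    {
                        "period": f"{lo}-{hi}",
                        "family": fit.family,
                        "shape": fit.shape,
                        "scale": fit.scale,
                        "h": fit.h,
                        "n": fit.n,
                        "aic": gof.aic,
                        "ks": gof.ks,
                        "cvm": gof.cvm,
                    }
                )
            fitted_periods.append((f"{lo}-{hi}", cmp.best("aic")))
        table = pd.DataFrame(rows)
        path = out / "size_fits.csv"
        table.to_csv(path, index=False)
        bundle.tables["size_fits"] = path
        done(n_fits=len(rows), best_by_aic=dict(fitted_periods))
    except Exception as exc:
        raise StageError("size_distributions", exc) from exc

    # -- mean excess / threshold --------------------------------------------
    done = stage("threshold_selection")
    try:
        sizes = catalog.sizes[catalog.sizes >= config.min_fit_size].to_numpy()
        curve = mean_excess_curve(sizes, min_exceedances=SELECTION_MIN_EXCEEDANCES)
        pd.DataFrame(
            {"u": curve.thresholds, "mean_excess": curve.mean_excess, "n_exceed": curve.n_exceed}
        ).to_csv(out / "mean_excess.csv", index=False)
        bundle.tables["mean_excess"] = out / "mean_excess.csv"
        sel = select_threshold(curve, config.threshold_grid)
        _write_json(
            out / "threshold.json",
            {"threshold_acres": sel.threshold, "tail_slope": sel.slope, "tail_intercept": sel.intercept},
        )
        bundle.tables["threshold"] = out / "threshold.json"
        done(n_curve_points=int(curve.thresholds.size), threshold_acres=sel.threshold)
    except Exception as exc:
        raise StageError("threshold_selection", exc) from exc

    # -- temporal trends -----------------------------------------------------
    done = stage("temporal_trends")
    try:
        tidy = []
        fits: dict = {}
        peaks: dict = {}
        lo, hi = catalog.period
        for measure in ("frequency", "burned_area"):
            for group in GROUPS:
                series = annual_series(catalog, measure, group, threshold=config.size_threshold)
                for year, value in series.items():
                    tidy.append({"measure": measure, "group": group, "year": year, "value": value})
                key = f"{measure}_{group}"
                if lo < config.breakpoint <= hi and series[series.index < config.breakpoint].size >= 3:
                    seg = segmented_regression(series, config.breakpoint)
                    fits[key] = {
                        side: {
                            "slope": getattr(seg, side).slope,
                            "intercept": getattr(seg, side).intercept,
                            "r2": getattr(seg, side).r2,
                            "p_value": getattr(seg, side).p_value,
                            "band_lower": getattr(seg, side).band_lower,
                            "band_upper": getattr(seg, side).band_upper,
                            "years": getattr(seg, side).years,
                        }
                        for side in ("before", "after")
                    }
                else:
                    manifest["skips"].append(
                        f"temporal_trends: breakpoint {config.breakpoint} outside or at the edge "
                        f"of period {lo}-{hi}; segmented fit for {key} skipped"
                    )
                profile = monthly_profile(catalog, measure, group, threshold=config.size_threshold)
                try:
                    peaks[key] = peak_month(profile)
                except ValueError:
                    peaks[key] = None
        pd.DataFrame(tidy).to_csv(out / "annual_series.csv", index=False)
        bundle.tables["annual_series"] = out / "annual_series.csv"
        _write_json(out / "trend_fits.json", fits)
        _write_json(out / "peak_months.json", peaks)
        bundle.tables["trend_fits"] = out / "trend_fits.json"
        bundle.tables["peak_months"] = out / "peak_months.json"
        done(n_series=len(tidy), peak_months=peaks)
    except Exception as exc:
        raise StageError("temporal_trends", exc) from exc

    # -- kernel density maps --------------------------------------------------
    done = stage("kernel_density")
    try:
        radius = (
            config.kde_search_radius
            if config.kde_search_radius is not None
            else default_search_radius(catalog)
        )
        strata = {
            "all": catalog,
            "natural": filter_catalog(catalog, cause_groups=["natural"]),
            "human": filter_catalog(
                catalog,
                cause_groups=["human_transportation", "human_activity", "human_construction"],
            ),
        }
        n_maps = 0
        for stratum, sub in strata.items():
            if len(sub) == 0:
                manifest["skips"].append(f"kernel_density: stratum {stratum!r} empty; maps skipped")
                continue
            for mode in ("unit", "burned_area"):
                params = KDEParams(
                    search_radius=radius, cell_size=config.kde_cell_size, weight_mode=mode
                )
                raster = kernel_density(sub, params)
                path = out / f"kde_{stratum}_{mode}.asc"
                write_ascii_grid(raster, path)
                bundle.rasters[f"kde_{stratum}_{mode}"] = path
                n_maps += 1
        done(search_radius_m=radius, n_maps=n_maps)
    except Exception as exc:
        raise StageError("kernel_density", exc) from exc

    # -- covariate analysis ----------------------------------------------------
    if stack is None:
        manifest["skips"].append("covariate_analysis: no covariate stack provided; stage skipped")
    else:
        done = stage("covariate_analysis")
        try:
            corr = raster_correlation(stack)
            corr.to_frame().to_csv(out / "correlation_matrix.csv")
            bundle.tables["correlation_matrix"] = out / "correlation_matrix.csv"
            screen = filter_correlated(
                corr, threshold=config.correlation_threshold, keep_rules=config.keep_rules
            )
            _write_json(
                out / "retained_variables.json",
                {"retained": screen.retained, "removed": screen.removed, "log": screen.log},
            )
            bundle.tables["retained_variables"] = out / "retained_variables.json"

            grid = grid_aggregate(catalog, stack, cell_size=config.grid_cell_size)
            grid.table.to_csv(out / "grid_dataset.csv", index=False)
            bundle.tables["grid_dataset"] = out / "grid_dataset.csv"

            comp = pca(grid.table[list(screen.retained)], standardize=True)
            comp.loadings.to_csv(out / "pca_loadings.csv")
            _write_json(
                out / "pca_variance.json",
                {"eigenvalues": comp.eigenvalues, "explained": comp.explained, "cumulative": comp.cumulative},
            )
            bundle.tables["pca_loadings"] = out / "pca_loadings.csv"
            bundle.tables["pca_variance"] = out / "pca_variance.json"

            fit = logistic_fit(grid, list(screen.retained))
            coef = pd.DataFrame(
                {
                    "coefficient": fit.coefficients,
                    "std_error": fit.std_errors,
                    "p_value": fit.p_values,
                }
            )
            coef.index.name = "variable"
            coef.to_csv(out / "logistic_coefficients.csv")
            bundle.tables["logistic_coefficients"] = out / "logistic_coefficients.csv"
            done(
                n_variables=len(corr.names),
                retained=list(screen.retained),
                n_cells=len(grid.table),
                presence_rate=float(grid.table["presence"].mean()),
                logit_converged=fit.converged,
                separation=fit.separation,
            )
        except Exception as exc:
            raise StageError("covariate_analysis", exc) from exc

    _write_json(out / "manifest.json", manifest)
    bundle.manifest = manifest
    return bundle
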