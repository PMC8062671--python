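"""Fire event catalogs: records, cause taxonomy, filtering rules, and I/O.

A catalog is an ordered collection of ignition events, each reduced to a
point location in a projected planar CRS (meters), a discovery date at
year/month precision, a burned area in acres, a raw ignition-cause code from
a closed vocabulary, and an optional fuel type.  Fire-perimeter databases
typically apply fuel-dependent minimum-size inclusion rules (10 acres for
timber, 30 for brush, 300 for grass fires); :func:`filter_catalog` can apply
the same rule so that synthetic catalogs match the record structure of the
real archives.

The raw cause vocabulary and its grouping into six cause groups (natural,
three human-caused subgroups, miscellaneous, unknown) are loaded from a
versioned YAML mapping shipped with the package, so the taxonomy is data,
not code.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "ACRE_TO_KM2",
    "CAUSE_GROUPS",
    "DB_MIN_SIZE_ACRES",
    "FUEL_TYPES",
    "CatalogError",
    "SchemaError",
    "RowError",
    "EmptyCatalogError",
    "CauseError",
    "FireRecord",
    "FireCatalog",
    "CauseSummary",
    "acres_to_km2",
    "cause_vocabulary",
    "classify_cause",
    "cause_binary",
    "read_catalog",
    "write_catalog",
    "filter_catalog",
    "split_by_size",
    "summarize_causes",
]

logger = logging.getLogger(__name__)

#: International acre in square kilometers (exact).
ACRE_TO_KM2 = 0.0040468564224

#: The six cause groups, in reporting order.
CAUSE_GROUPS = (
    "natural",
    "human_transportation",
    "human_activity",
    "human_construction",
    "miscellaneous",
    "unknown",
)

#: Fuel-dependent minimum burned area (acres) for database inclusion.
DB_MIN_SIZE_ACRES: Mapping[str, float] = {"timber": 10.0, "brush": 30.0, "grass": 300.0}

FUEL_TYPES = ("timber", "brush", "grass")

_CSV_COLUMNS = ["id", "x", "y", "year", "month", "size_acres", "cause", "fuel"]


class CatalogError(ValueError):
    """Base class for catalog-layer errors."""


class SchemaError(CatalogError):
    """A required column or field is missing from an input file."""


class RowError(CatalogError):
    """One or more rows failed validation; carries row-level diagnostics."""

    def __init__(self, diagnostics: Sequence[str]):
        super().__init__("; ".join(diagnostics))
        self.diagnostics = list(diagnostics)


class EmptyCatalogError(CatalogError):
    """An operation that needs records received none."""


class CauseError(CatalogError):
    """A cause code outside the closed vocabulary."""


# ---------------------------------------------------------------------------
# Cause taxonomy
# ---------------------------------------------------------------------------

_CAUSE_MAP: dict[str, str] | None = None


def cause_vocabulary() -> dict[str, str]:
    """Return the mapping raw cause code -> cause group (cached)."""
    global _CAUSE_MAP
    if _CAUSE_MAP is None:
        text = resources.files("firestats.data").joinpath("cause_codes.yaml").read_text()
        spec = yaml.safe_load(text)
        mapping: dict[str, str] = {}
        for group, codes in spec["groups"].items():
            if group not in CAUSE_GROUPS:
                raise CauseError(f"unknown cause group in vocabulary file: {group!r}")
            for code in codes:
                if code in mapping:
                    raise CauseError(f"cause code {code!r} mapped twice")
                mapping[code] = group
        _CAUSE_MAP = mapping
    return _CAUSE_MAP


def classify_cause(cause_code: str) -> str:
    """Map a raw cause code to its cause group.

    The mapping is total and deterministic over the closed vocabulary;
    an unknown code raises :class:`CauseError` naming the code.
    """
    try:
        return cause_vocabulary()[cause_code]
    except KeyError:
        raise CauseError(f"cause code not in vocabulary: {cause_code!r}") from None


def cause_binary(cause_code: str) -> str | None:
    """Binary natural/human view of a cause code.

    Returns ``"natural"`` for lightning, ``"human"`` for the fifteen
    anthropogenic codes, and ``None`` for miscellaneous/unknown causes,
    which stand outside the dichotomy.
    """
    group = classify_cause(cause_code)
    if group == "natural":
        return "natural"
    if group.startswith("human_"):
        return "human"
    return None


# ---------------------------------------------------------------------------
# Records and catalogs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FireRecord:
    """One ignition event.

    Coordinates are planar (meters) in whatever projected CRS the catalog
    declares; no geodesy is performed.  Dates carry year/month precision.
    """

    id: str
    x: float
    y: float
    year: int
    month: int
    size_acres: float
    cause: str
    fuel: str | None = None

    def validate(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise CatalogError(f"record {self.id}: non-finite coordinates")
        if not (self.size_acres > 0 and math.isfinite(self.size_acres)):
            raise CatalogError(f"record {self.id}: size must be positive, got {self.size_acres}")
        if not 1 <= int(self.month) <= 12:
            raise CatalogError(f"record {self.id}: month {self.month} outside 1..12")
        classify_cause(self.cause)
        if self.fuel is not None and self.fuel not in FUEL_TYPES:
            raise CatalogError(f"record {self.id}: unknown fuel type {self.fuel!r}")


@dataclass(frozen=True)
class FireCatalog:
    """Ordered, immutable collection of :class:`FireRecord`.

    ``period`` is the (min year, max year) span the catalog covers; it
    defaults to the span of the records but may be declared wider (so that
    fire-free years at the edges are represented downstream).
    """

    records: tuple[FireRecord, ...]
    crs_note: str = "unspecified planar CRS (meters)"
    period: tuple[int, int] | None = None
    diagnostics: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise CatalogError("record ids are not unique")
        if self.records:
            lo = min(r.year for r in self.records)
            hi = max(r.year for r in self.records)
            if self.period is None:
                object.__setattr__(self, "period", (lo, hi))
            elif not (self.period[0] <= lo and hi <= self.period[1]):
                raise CatalogError(
                    f"declared period {self.period} does not cover record years [{lo}, {hi}]"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FireRecord]:
        return iter(self.records)

    @classmethod
    def from_records(
        cls,
        records: Iterable[FireRecord],
        crs_note: str = "unspecified planar CRS (meters)",
        period: tuple[int, int] | None = None,
    ) -> "FireCatalog":
        recs = tuple(records)
        for r in recs:
            r.validate()
        return cls(records=recs, crs_note=crs_note, period=period)

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view with one row per record (columns as the CSV dialect)."""
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "x": [r.x for r in self.records],
                "y": [r.y for r in self.records],
                "year": [r.year for r in self.records],
                "month": [r.month for r in self.records],
                "size_acres": [r.size_acres for r in self.records],
                "cause": [r.cause for r in self.records],
                "fuel": [r.fuel for r in self.records],
            }
        )

    @property
    def sizes(self) -> pd.Series:
        return pd.Series([r.size_acres for r in self.records], dtype=float)


@dataclass(frozen=True)
class CauseSummary:
    """Per-group counts and percentages over a catalog."""

    counts: Mapping[str, int]
    percentages: Mapping[str, float]
    total: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": list(CAUSE_GROUPS),
                "count": [self.counts[g] for g in CAUSE_GROUPS],
                "percentage": [self.percentages[g] for g in CAUSE_GROUPS],
            }
        )


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------


def acres_to_km2(acres: float) -> float:
    """Convert burned area from acres to square kilometers.

    Uses the international acre, 1 acre = 0.0040468564224 km² exactly;
    sign-preserving for signed differences.
    """
    return acres * ACRE_TO_KM2


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _record_from_row(idx, row: Mapping) -> FireRecord:
    fuel = row.get("fuel")
    if fuel is None or (isinstance(fuel, float) and math.isnan(fuel)) or fuel == "":
        fuel = None
    rec = FireRecord(
        id=str(row["id"]),
        x=float(row["x"]),
        y=float(row["y"]),
        year=int(row["year"]),
        month=int(row["month"]),
        size_acres=float(row["size_acres"]),
        cause=str(row["cause"]),
        fuel=fuel,
    )
    rec.validate()
    return rec


def read_catalog(path: str | Path, format: str | None = None) -> FireCatalog:
    """Read a fire catalog from CSV or GeoJSON.

    Invalid rows are rejected individually; their diagnostics are logged and
    kept on ``catalog.diagnostics``.  A missing column raises
    :class:`SchemaError`; an empty file raises :class:`EmptyCatalogError`.
    """
    path = Path(path)
    if format is None:
        format = "geojson" if path.suffix.lower() in {".geojson", ".json"} else "csv"
    if format == "csv":
        try:
            frame = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            raise EmptyCatalogError(f"empty catalog file: {path}") from None
        missing = [c for c in _CSV_COLUMNS if c not in frame.columns and c != "fuel"]
        if missing:
            raise SchemaError(f"missing required columns {missing} in {path}")
        rows = frame.to_dict("records")
    elif format == "geojson":
        payload = json.loads(path.read_text())
        features = payload.get("features", [])
        if not features:
            raise EmptyCatalogError(f"no features in {path}")
        rows = []
        for feat in features:
            props = dict(feat.get("properties", {}))
            coords = feat.get("geometry", {}).get("coordinates", [None, None])
            props.setdefault("x", coords[0])
            props.setdefault("y", coords[1])
            rows.append(props)
        missing = {"id", "year", "month", "size_acres", "cause"} - set(rows[0])
        if missing:
            raise SchemaError(f"missing required properties {sorted(missing)} in {path}")
    else:
        raise ValueError(f"unknown catalog format: {format!r}")

    records: list[FireRecord] = []
    diagnostics: list[str] = []
    for idx, row in enumerate(rows):
        try:
            records.append(_record_from_row(idx, row))
        except (CatalogError, KeyError, TypeError, ValueError) as exc:
            diagnostics.append(f"row {idx}: {exc}")
    if diagnostics:
        logger.warning("rejected %d rows while reading %s", len(diagnostics), path)
    if not records:
        raise EmptyCatalogError(f"no valid records in {path}")
    cat = FireCatalog.from_records(records)
    object.__setattr__(cat, "diagnostics", tuple(diagnostics))
    return cat


def write_catalog(catalog: FireCatalog, path: str | Path, format: str | None = None) -> None:
    """Write a catalog as CSV or GeoJSON (Point features)."""
    path = Path(path)
    if format is None:
        format = "geojson" if path.suffix.lower() in {".geojson", ".json"} else "csv"
    if format == "csv":
        catalog.to_dataframe().to_csv(path, index=False)
    elif format == "geojson":
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [r.x, r.y]},
                "properties": {
                    "id": r.id,
                    "year": r.year,
                    "month": r.month,
                    "size_acres": r.size_acres,
                    "cause": r.cause,
                    "fuel": r.fuel,
                },
            }
            for r in catalog
        ]
        payload = {
            "type": "FeatureCollection",
            "crs_note": catalog.crs_note,
            "features": features,
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown catalog format: {format!r}")


# ---------------------------------------------------------------------------
# Filtering and partitioning
# ---------------------------------------------------------------------------


def filter_catalog(
    catalog: FireCatalog,
    period: tuple[int, int] | None = None,
    min_size_rule: Mapping[str, float] | bool | None = None,
    cause_groups: Sequence[str] | None = None,
) -> FireCatalog:
    """Return a new catalog with only the records satisfying all criteria.

    Parameters
    ----------
    period
        Inclusive (start year, end year).
    min_size_rule
        Fuel-dependent minimum sizes in acres; ``True`` applies the standard
        database inclusion rule (:data:`DB_MIN_SIZE_ACRES`).  Records with no
        fuel type are held to the smallest listed minimum.
    cause_groups
        Keep only records whose cause group is in this set.

    Order is preserved and the input catalog is untouched.
    """
    if period is not None and period[0] > period[1]:
        raise ValueError(f"inverted period bounds: {period}")
    if min_size_rule is True:
        min_size_rule = DB_MIN_SIZE_ACRES
    elif min_size_rule is False:
        min_size_rule = None
    if cause_groups is not None:
        bad = set(cause_groups) - set(CAUSE_GROUPS)
        if bad:
            raise ValueError(f"unknown cause groups: {sorted(bad)}")
    fallback_min = min(min_size_rule.values()) if min_size_rule else 0.0

    kept = []
    for rec in catalog:
        if period is not None and not (period[0] <= rec.year <= period[1]):
            continue
        if min_size_rule is not None:
            floor = min_size_rule.get(rec.fuel, fallback_min) if rec.fuel else fallback_min
            if rec.size_acres < floor:
                continue
        if cause_groups is not None and classify_cause(rec.cause) not in cause_groups:
            continue
        kept.append(rec)
    out_period = period if period is not None else catalog.period
    return FireCatalog(records=tuple(kept), crs_note=catalog.crs_note, period=out_period if kept else None)


def split_by_size(catalog: FireCatalog, threshold: float) -> tuple[FireCatalog, FireCatalog]:
    """Partition into (large, small) catalogs at a size threshold.

    A large fire has burned area **at or above** the threshold (the ≥
    convention, consistent with class-based size taxonomies where a class
    contains its lower bound).  The partition is exact: every record lands
    in exactly one half.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    large = tuple(r for r in catalog if r.size_acres >= threshold)
    small = tuple(r for r in catalog if r.size_acres < threshold)
    mk = lambda recs: FireCatalog(records=recs, crs_note=catalog.crs_note)
    return mk(large), mk(small)


def summarize_causes(catalog: FireCatalog) -> CauseSummary:
    """Counts and percentages per cause group (percentages to 2 decimals)."""
    if len(catalog) == 0:
        raise EmptyCatalogError("cannot summarize an empty catalog")
    counts = {g: 0 for g in CAUSE_GROUPS}
    for rec in catalog:
        counts[classify_cause(rec.cause)] += 1
    total = len(catalog)
    pct = {g: round(100.0 * counts[g] / total, 2) for g in CAUSE_GROUPS}
    return CauseSummary(counts=counts, percentages=pct, total=total)
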