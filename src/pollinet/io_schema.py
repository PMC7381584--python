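"""Domain types, CSV schemas, validation, and load-time filtering.

All downstream stages consume the canonical tables produced here: raw
per-group visit counts are collapsed into a single (honey_bee, wild)
pair at load, and taxa flagged for exclusion are removed before any
model sees the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Visitor groups recorded per observation period, in canonical order.
VISITOR_GROUPS = (
    "honey_bee",
    "other_bee_wasp",
    "fly",
    "butterfly_moth",
    "ant",
    "true_bug",
)

#: Groups always excluded from analysis.
EXCLUDED_GROUPS = ("ant", "true_bug")

#: Groups pooled into the "wild pollinator" count (honey bees excluded).
WILD_GROUPS = ("other_bee_wasp", "fly", "butterfly_moth")

NATIVE_STATUSES = ("native", "introduced", "excluded")

POLLINATOR_TYPES = ("honey_bee", "wild")


class SchemaError(ValueError):
    """A table is structurally unusable (e.g. missing required column)."""


@dataclass(frozen=True)
class PlantSpecies:
    plant_id: str
    name: str
    native_status: str  # one of NATIVE_STATUSES

    def __post_init__(self) -> None:
        if self.native_status not in NATIVE_STATUSES:
            raise ValueError(
                f"native_status {self.native_status!r} not in {NATIVE_STATUSES}"
            )


@dataclass(frozen=True)
class ObservationPeriod:
    """One timed watch of one plant species at one site-week."""

    obs_id: str
    site: str
    week: int
    zone: str
    plant_id: str
    floral_units: int
    minutes: float
    visits: Mapping[str, int]          # inside-flower visits per group
    outside_flower: Mapping[str, int]  # visits outside the flower, dropped


@dataclass(frozen=True)
class StemCountRecord:
    site: str
    week: int
    zone: str
    plant_id: str
    stems: int  # flowering stems per 100 m^2 quadrat


@dataclass(frozen=True)
class FloralUnitRecord:
    site: str
    date: str
    plant_id: str
    stem_id: str
    floral_units_on_stem: int


@dataclass(frozen=True)
class NettingPeriod:
    netting_id: str
    site: str
    week: int
    zone: str
    plant_id: str
    minutes: float
    specimens: tuple[str, ...]


@dataclass(frozen=True)
class PollenCount:
    apiary_id: str
    round: int  # 1 or 2
    matrix: str  # "bee_bread" | "nectar"
    knapweed_grains: int
    total_grains: int


@dataclass
class ValidationReport:
    """Row-level outcomes of a table load."""

    n_read: dict[str, int] = field(default_factory=dict)
    n_rejected: dict[str, int] = field(default_factory=dict)
    rejections: list[tuple[str, int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    unknown_plant_ids: set[str] = field(default_factory=set)

    def reject(self, table: str, row: int, reason: str) -> None:
        self.n_rejected[table] = self.n_rejected.get(table, 0) + 1
        self.rejections.append((table, row, reason))

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        log.warning(message)


@dataclass
class TableBundle:
    """Validated, typed tables ready for analysis."""

    plants: pd.DataFrame | None = None
    observations: pd.DataFrame | None = None
    stems: pd.DataFrame | None = None
    floral_units: pd.DataFrame | None = None
    netting: pd.DataFrame | None = None
    pollen: pd.DataFrame | None = None
    report: ValidationReport = field(default_factory=ValidationReport)


# ---------------------------------------------------------------------------
# per-table schemas: required columns and dtypes

_VISIT_COLS = [f"visits_{g}" for g in VISITOR_GROUPS]
_OUTSIDE_COLS = [f"outside_{g}" for g in VISITOR_GROUPS]

SCHEMAS: dict[str, dict] = {
    "plants": {"required": ["plant_id", "name", "native_status"]},
    "observations": {
        "required": ["obs_id", "site", "week", "zone", "plant_id",
                     "floral_units", "minutes", *_VISIT_COLS],
        "optional": _OUTSIDE_COLS,
    },
    "stems": {"required": ["site", "week", "zone", "plant_id", "stems"]},
    "floral_units": {
        "required": ["site", "date", "plant_id", "stem_id",
                     "floral_units_on_stem"],
    },
    "netting": {
        "required": ["netting_id", "site", "week", "zone", "plant_id",
                     "minutes", "specimens"],
    },
    "pollen": {
        "required": ["apiary_id", "round", "matrix", "knapweed_grains",
                     "total_grains"],
    },
}

#: observation periods shorter than this draw a soft warning, not an error
MIN_FLORAL_UNITS_SOFT = 10
ALLOWED_MINUTES = (5.0, 10.0, 15.0)
EXPECTED_POLLEN_TOTAL = 300


def _check_columns(df: pd.DataFrame, table: str,
                   report: ValidationReport) -> pd.DataFrame:
    spec = SCHEMAS[table]
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")
    known = set(spec["required"]) | set(spec.get("optional", []))
    extra = [c for c in df.columns if c not in known]
    if extra:
        report.warn(f"{table}: ignoring unknown column(s) {extra}")
        df = df.drop(columns=extra)
    for c in spec.get("optional", []):
        if c not in df.columns:
            df[c] = 0
    return df


def _nonneg_int(value) -> int:
    """Coerce to a non-negative integer or raise ValueError."""
    v = float(value)
    if not np.isfinite(v) or v < 0 or v != int(v):
        raise ValueError(f"expected non-negative integer, got {value!r}")
    return int(v)


def _validate_observations(df: pd.DataFrame, report: ValidationReport) -> pd.DataFrame:
    keep = []
    for idx, row in df.iterrows():
        try:
            fu = _nonneg_int(row["floral_units"])
            minutes = float(row["minutes"])
            if fu < 1:
                raise ValueError("floral_units < 1")
            if minutes <= 0:
                raise ValueError("minutes <= 0")
            for c in _VISIT_COLS + _OUTSIDE_COLS:
                _nonneg_int(row[c])
        except ValueError as e:
            report.reject("observations", int(idx), str(e))
            continue
        if fu < MIN_FLORAL_UNITS_SOFT:
            report.warn(
                f"observations row {idx}: only {fu} floral units observed "
                f"(< {MIN_FLORAL_UNITS_SOFT})"
            )
        if minutes not in ALLOWED_MINUTES:
            report.warn(
                f"observations row {idx}: unusual duration {minutes} min"
            )
        keep.append(idx)
    out = df.loc[keep].copy()
    out["week"] = out["week"].astype(int)
    out["floral_units"] = out["floral_units"].astype(int)
    out["minutes"] = out["minutes"].astype(float)
    for c in _VISIT_COLS + _OUTSIDE_COLS:
        out[c] = out[c].astype(int)
    return out.reset_index(drop=True)


def _validate_simple_counts(df: pd.DataFrame, table: str, count_cols: list[str],
                            report: ValidationReport) -> pd.DataFrame:
    keep = []
    for idx, row in df.iterrows():
        try:
            for c in count_cols:
                _nonneg_int(row[c])
        except ValueError as e:
            report.reject(table, int(idx), str(e))
            continue
        keep.append(idx)
    out = df.loc[keep].copy()
    for c in count_cols:
        out[c] = out[c].astype(int)
    return out.reset_index(drop=True)


def _validate_pollen(df: pd.DataFrame, report: ValidationReport) -> pd.DataFrame:
    keep = []
    for idx, row in df.iterrows():
        try:
            k = _nonneg_int(row["knapweed_grains"])
            t = _nonneg_int(row["total_grains"])
            r = _nonneg_int(row["round"])
            if k > t:
                raise ValueError("knapweed_grains > total_grains")
            if row["matrix"] not in ("bee_bread", "nectar"):
                raise ValueError(f"unknown matrix {row['matrix']!r}")
            if r not in (1, 2):
                raise ValueError(f"round must be 1 or 2, got {r}")
        except ValueError as e:
            report.reject("pollen", int(idx), str(e))
            continue
        if t != EXPECTED_POLLEN_TOTAL:
            report.warn(f"pollen row {idx}: total_grains={t} != "
                        f"{EXPECTED_POLLEN_TOTAL}")
        keep.append(idx)
    out = df.loc[keep].copy()
    out["round"] = out["round"].astype(int)
    out["knapweed_grains"] = out["knapweed_grains"].astype(int)
    out["total_grains"] = out["total_grains"].astype(int)
    return out.reset_index(drop=True)


def _validate_plants(df: pd.DataFrame, report: ValidationReport) -> pd.DataFrame:
    keep = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        pid = str(row["plant_id"])
        if pid in seen:
            report.reject("plants", int(idx), f"duplicate plant_id {pid!r}")
            continue
        if row["native_status"] not in NATIVE_STATUSES:
            report.reject("plants", int(idx),
                          f"native_status {row['native_status']!r} invalid")
            continue
        seen.add(pid)
        keep.append(idx)
    return df.loc[keep].reset_index(drop=True)


def read_tables(paths: Mapping[str, str | Path]) -> TableBundle:
    """Read and validate the CSV inputs named in *paths*.

    Parameters
    ----------
    paths
        Mapping from table name (keys of :data:`SCHEMAS`) to a CSV path.
        Any subset of tables may be supplied.

    Returns
    -------
    TableBundle
        Validated dataframes plus a row-level :class:`ValidationReport`.
        A missing required column is a hard :class:`SchemaError`; an
        invariant breach rejects the offending row and logs the reason.
    """
    bundle = TableBundle()
    report = bundle.report
    for table, path in paths.items():
        if table not in SCHEMAS:
            raise SchemaError(f"unknown table name {table!r}")
        df = pd.read_csv(path)
        report.n_read[table] = len(df)
        df = _check_columns(df, table, report)
        if table == "plants":
            df = _validate_plants(df, report)
        elif table == "observations":
            df = _validate_observations(df, report)
        elif table == "stems":
            df = _validate_simple_counts(df, "stems", ["stems"], report)
        elif table == "floral_units":
            df = _validate_simple_counts(df, "floral_units",
                                         ["floral_units_on_stem"], report)
        elif table == "netting":
            df = df.copy()
            df["specimens"] = df["specimens"].fillna("")
        elif table == "pollen":
            df = _validate_pollen(df, report)
        setattr(bundle, table, df)

    # collect plant ids referenced but not declared
    if bundle.plants is not None:
        known = set(bundle.plants["plant_id"].astype(str))
        for t in ("observations", "stems", "netting"):
            df = getattr(bundle, t)
            if df is not None:
                report.unknown_plant_ids |= (
                    set(df["plant_id"].astype(str)) - known
                )
        if report.unknown_plant_ids:
            report.warn(
                f"plant ids not in plants table: "
                f"{sorted(report.unknown_plant_ids)}"
            )
    return bundle


def filter_visits(observations: pd.DataFrame,
                  include_wasps: bool = True) -> pd.DataFrame:
    """Collapse per-group visit counts to (honey_bee_visits, wild_visits).

    Ants and true bugs are excluded; outside-flower contacts are dropped
    for all groups (the per-group ``visits_*`` columns already hold
    inside-flower counts, so the ``outside_*`` columns are simply not
    summed). Idempotent: a table that already carries the two canonical
    columns is returned unchanged.

    ``include_wasps=False`` removes the pooled bee/wasp group from the
    wild total (config toggle; the default pools all non-honey-bee
    groups).
    """
    if {"honey_bee_visits", "wild_visits"} <= set(observations.columns):
        return observations
    wild_groups = list(WILD_GROUPS)
    if not include_wasps:
        wild_groups = [g for g in wild_groups if g != "other_bee_wasp"]
    out = observations.copy()
    out["honey_bee_visits"] = out["visits_honey_bee"]
    out["wild_visits"] = sum(out[f"visits_{g}"] for g in wild_groups)
    drop = [c for c in out.columns
            if c.startswith("visits_") or c.startswith("outside_")]
    return out.drop(columns=drop)


def exclude_status_both(plants: pd.DataFrame,
                        *tables: pd.DataFrame) -> tuple[pd.DataFrame, ...]:
    """Remove plants with ``native_status == "excluded"`` everywhere.

    Returns ``(plants, *tables)`` with all records referencing an
    excluded taxon dropped; the number of removals is logged.
    """
    excluded = set(
        plants.loc[plants["native_status"] == "excluded", "plant_id"]
        .astype(str)
    )
    plants_out = plants[~plants["plant_id"].astype(str).isin(excluded)]
    plants_out = plants_out.reset_index(drop=True)
    outs = [plants_out]
    n_dropped = 0
    for df in tables:
        mask = df["plant_id"].astype(str).isin(excluded)
        n_dropped += int(mask.sum())
        outs.append(df[~mask].reset_index(drop=True))
    if excluded:
        log.info("excluded %d species (%d dependent records dropped)",
                 len(excluded), n_dropped)
    if len(plants_out) == 0:
        warnings.warn("all plant species were excluded; analysis tables "
                      "are empty", stacklevel=2)
    return tuple(outs)


def iso_week(dates: Iterable) -> pd.Series:
    """ISO week index for date-like values (used when only dates are given)."""
    return pd.to_datetime(pd.Series(list(dates))).dt.isocalendar().week.astype(int)


def write_bundle(bundle: TableBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every present table as CSV; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for table in SCHEMAS:
        df = getattr(bundle, table)
        if df is not None:
            p = out_dir / f"{table}.csv"
            df.to_csv(p, index=False)
            written[table] = p
    return written


def split_specimens(field_value: str) -> tuple[str, ...]:
    """Parse the semicolon-separated specimen list of a netting row."""
    if not isinstance(field_value, str) or not field_value.strip():
        return ()
    return tuple(s.strip() for s in field_value.split(";") if s.strip())


def normalize_taxon(label: str,
                    synonyms: Mapping[str, str] | None = None) -> str:
    """Case-insensitive taxon normalization with optional synonym table.

    Unresolved labels are kept verbatim (lower-cased) and act as
    morphotypes — distinct taxa in diversity calculations.
    """
    key = label.strip().lower()
    if synonyms:
        lowered = {k.strip().lower(): v for k, v in synonyms.items()}
        return lowered.get(key, key)
    return key
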