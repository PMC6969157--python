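"""Table schemas, validated CSV readers/writers, and unit/basis normalization.

Every table crosses this boundary as a tidy :class:`pandas.DataFrame` in
canonical units: biomass in Tg (1 Tg = 10^6 tonnes), phosphorus content as a
wet-basis mass fraction, and efficiencies as dimensionless fractions.
Conversions (tonnes -> Tg, dry -> wet basis, brackish -> marine) happen here
and only here; downstream modules assume canonical units throughout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

TG_PER_TONNE = 1.0e-6

MAJOR_GROUPS = ("finfish", "crustacean", "mollusk")
EXTENDED_GROUPS = MAJOR_GROUPS + ("other-invertebrate", "aquatic-plant", "mammal")
#: groups excluded from the phosphorus budget (readable, dropped downstream)
NON_FISH_GROUPS = ("aquatic-plant", "mammal")
ENVIRONMENTS = ("freshwater", "marine")
SOURCES = ("capture", "aquaculture")
#: the six environment x taxon keys indexing culture-system PUE pools
GROUP6 = tuple(f"{env}_{taxon}" for env in ENVIRONMENTS for taxon in MAJOR_GROUPS)

#: wet-basis whole-body P mass fractions above this are considered data errors
WET_CONC_MAX = 0.1


class SchemaError(ValueError):
    """A table failed validation against its schema."""


class ConfigError(ValueError):
    """Invalid configuration values."""


@dataclass(frozen=True)
class Column:
    """One column contract within a :class:`TableSchema`."""

    name: str
    kind: str = "str"  # "str" | "int" | "float"
    nullable: bool = False
    optional: bool = False  # whole column may be absent from the file
    vocab: tuple[str, ...] | None = None
    minimum: float | None = None
    maximum: float | None = None
    exclusive_min: bool = False
    exclusive_max: bool = False


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[Column, ...]

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)


PRODUCTION_SCHEMA = TableSchema(
    "production",
    (
        Column("year", "int"),
        Column("country", "str"),
        Column("species", "str"),
        Column("order", "str", nullable=True, optional=True),
        Column("group", "str", vocab=EXTENDED_GROUPS),
        Column("environment", "str", vocab=("freshwater", "marine", "brackish")),
        Column("source", "str", vocab=SOURCES),
        Column("weight", "float", minimum=0.0),
        Column("unit", "str", nullable=True, optional=True,
               vocab=("Tg", "tonnes", "t")),
    ),
)

CONCENTRATION_SCHEMA = TableSchema(
    "concentration",
    (
        Column("species", "str"),
        Column("order", "str", nullable=True),
        Column("group", "str", vocab=MAJOR_GROUPS),
        Column("value", "float", minimum=0.0, exclusive_min=True),
        Column("basis", "str", vocab=("wet", "dry")),
        Column("moisture", "float", nullable=True, optional=True,
               minimum=0.0, maximum=1.0, exclusive_min=True, exclusive_max=True),
        Column("origin", "str", nullable=True, optional=True,
               vocab=("wild", "raised")),
    ),
)

PUE_SCHEMA = TableSchema(
    "pue",
    (
        Column("group6", "str", vocab=GROUP6),
        Column("value", "float", minimum=0.0, maximum=1.67, exclusive_min=True),
        Column("system", "str", nullable=True, optional=True),
        Column("country", "str", nullable=True, optional=True),
    ),
)

PRE_SCHEMA = TableSchema(
    "pre",
    (
        Column("group", "str", vocab=MAJOR_GROUPS),
        Column("value", "float", minimum=0.0, maximum=1.0, exclusive_min=True),
    ),
)

SCALING_SCHEMA = TableSchema(
    "scaling",
    (
        Column("country", "str"),
        Column("year", "int"),
        Column("factor", "float", minimum=0.0, exclusive_min=True),
    ),
)

REGION_SCHEMA = TableSchema(
    "region",
    (
        Column("country", "str"),
        Column("region", "str"),
        Column("year_start", "int", nullable=True, optional=True),
        Column("year_end", "int", nullable=True, optional=True),
    ),
)

SCHEMAS: dict[str, TableSchema] = {
    s.name: s
    for s in (
        PRODUCTION_SCHEMA,
        CONCENTRATION_SCHEMA,
        PUE_SCHEMA,
        PRE_SCHEMA,
        SCALING_SCHEMA,
        REGION_SCHEMA,
    )
}


def _validate_column(schema: TableSchema, col: Column, series: pd.Series) -> pd.Series:
    """Coerce and validate one column, raising :class:`SchemaError` naming the
    first offending row."""
    s = series
    if col.kind in ("int", "float"):
        stripped = s.astype("string").str.strip() if s.dtype == object else s
        v = pd.to_numeric(s, errors="coerce")
        if s.dtype == object:
            bad = v.isna() & stripped.notna() & (stripped != "")
            if bad.any():
                i = int(bad.idxmax())
                raise SchemaError(
                    f"{schema.name}: row {i}: field {col.name!r} has "
                    f"non-numeric value {s[i]!r}"
                )
        s = v
    if not col.nullable and s.isna().any():
        i = int(s.isna().idxmax())
        raise SchemaError(f"{schema.name}: row {i}: field {col.name!r} is missing")
    if col.vocab is not None:
        bad = s.notna() & ~s.isin(col.vocab)
        if bad.any():
            i = int(bad.idxmax())
            raise SchemaError(
                f"{schema.name}: row {i}: field {col.name!r} value {s[i]!r} "
                f"not in {col.vocab}"
            )
    if col.minimum is not None:
        bad = s.notna() & ((s < col.minimum) | (col.exclusive_min & (s == col.minimum)))
        if bad.any():
            i = int(bad.idxmax())
            op = ">" if col.exclusive_min else ">="
            raise SchemaError(
                f"{schema.name}: row {i}: field {col.name!r} value {s[i]!r} "
                f"must be {op} {col.minimum}"
            )
    if col.maximum is not None:
        bad = s.notna() & ((s > col.maximum) | (col.exclusive_max & (s == col.maximum)))
        if bad.any():
            i = int(bad.idxmax())
            op = "<" if col.exclusive_max else "<="
            raise SchemaError(
                f"{schema.name}: row {i}: field {col.name!r} value {s[i]!r} "
                f"must be {op} {col.maximum}"
            )
    if col.kind == "int" and s.notna().all():
        s = s.astype(np.int64)
    return s


def validate_table(df: pd.DataFrame, schema: TableSchema) -> pd.DataFrame:
    """Validate a DataFrame against ``schema`` and return canonical columns."""
    missing = [c.name for c in schema.columns
               if not c.optional and c.name not in df.columns]
    if missing:
        raise SchemaError(f"{schema.name}: missing column(s) {missing}")
    out = {}
    for col in schema.columns:
        if col.name not in df.columns:
            continue
        out[col.name] = _validate_column(schema, col, df[col.name])
    result = pd.DataFrame(out)
    if schema.name == "production":
        result = _normalize_production(result)
    return result


def _normalize_production(df: pd.DataFrame) -> pd.DataFrame:
    """Fold brackish into marine and convert tonnage to Tg in place."""
    df = df.copy()
    if "unit" in df.columns:
        unit = df["unit"].fillna("Tg")
        in_tonnes = unit.isin(["tonnes", "t"])
        df.loc[in_tonnes, "weight"] = df.loc[in_tonnes, "weight"] * TG_PER_TONNE
        df["unit"] = "Tg"
    df.loc[df["environment"] == "brackish", "environment"] = "marine"
    return df


def read_table(path: str | Path, schema: TableSchema | str) -> pd.DataFrame:
    """Read and validate a CSV against one of the five table schemas."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{schema.name} table not found: {path}")
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    try:
        return validate_table(raw, schema)
    except SchemaError as err:
        raise SchemaError(f"{path}: {err}") from err


def write_table(df: pd.DataFrame, path: str | Path,
                schema: TableSchema | str | None = None) -> Path:
    """Write a table as CSV with canonical column order; returns the path."""
    path = Path(path)
    if schema is not None:
        if isinstance(schema, str):
            schema = SCHEMAS[schema]
        ordered = [c for c in schema.column_names if c in df.columns]
        extras = [c for c in df.columns if c not in ordered]
        df = df[ordered + extras]
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_production(path): return read_table(path, PRODUCTION_SCHEMA)
def read_concentrations(path): return read_table(path, CONCENTRATION_SCHEMA)
def read_pue(path): return read_table(path, PUE_SCHEMA)
def read_pre(path): return read_table(path, PRE_SCHEMA)
def read_scaling(path): return read_table(path, SCALING_SCHEMA)
def read_region_map(path): return read_table(path, REGION_SCHEMA)


def to_wet_basis(value: float, basis: str, moisture: float | None = None,
                 mean_moisture: float | None = None) -> float:
    """Convert one P concentration to wet (live-weight) basis.

    Wet records are returned unchanged. Dry records are multiplied by
    ``1 - moisture``; when the record carries no moisture, the database-average
    moisture ``mean_moisture`` is used instead.
    """
    if basis == "wet":
        return float(value)
    if basis != "dry":
        raise SchemaError(f"unknown concentration basis {basis!r}")
    m = moisture
    if m is None or (isinstance(m, float) and np.isnan(m)):
        m = mean_moisture
    if m is None or (isinstance(m, float) and np.isnan(m)):
        raise SchemaError(
            "dry-basis record without moisture and no database mean available"
        )
    if not 0.0 < float(m) < 1.0:
        raise SchemaError(f"moisture {m!r} outside (0, 1)")
    return float(value) * (1.0 - float(m))


def mean_moisture(concentrations: pd.DataFrame) -> float:
    """Average moisture content across all records that report it."""
    if "moisture" not in concentrations.columns:
        return float("nan")
    return float(concentrations["moisture"].mean())


def normalize_concentrations(concentrations: pd.DataFrame) -> pd.DataFrame:
    """Return the concentration table with every record on wet basis.

    Idempotent: applying it to its own output is a no-op.
    """
    out = concentrations.copy()
    dry = out["basis"] == "dry"
    if dry.any():
        db_moisture = mean_moisture(out)
        moist = out["moisture"] if "moisture" in out.columns else pd.Series(
            np.nan, index=out.index)
        out.loc[dry, "value"] = [
            to_wet_basis(v, "dry", m, db_moisture)
            for v, m in zip(out.loc[dry, "value"], moist[dry])
        ]
        out.loc[dry, "basis"] = "wet"
    too_high = out["value"] >= WET_CONC_MAX
    if too_high.any():
        i = int(too_high.idxmax())
        raise SchemaError(
            f"concentration: row {i}: wet-basis value {out['value'][i]!r} "
            f"exceeds plausible bound {WET_CONC_MAX}"
        )
    return out


# ---------------------------------------------------------------------------
# run manifests

def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, *, inputs: Mapping[str, Any] | None = None,
                   config: Mapping[str, Any] | None = None,
                   seed: int | None = None,
                   counts: Mapping[str, int] | None = None,
                   extra: Mapping[str, Any] | None = None) -> Path:
    """Record input hashes, config, seed, and row counts for one run."""
    from fishp import __version__

    manifest: dict[str, Any] = {
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": dict(config) if config else {},
        "counts": dict(counts) if counts else {},
    }
    if inputs:
        manifest["inputs"] = {
            name: {"path": str(p), "sha256": sha256_of(p)}
            for name, p in inputs.items()
        }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
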