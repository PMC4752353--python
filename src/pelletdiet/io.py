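"""Readers and writers for the tabular inputs and outputs.

The canonical on-disk form is a *wide* CSV: one row per pellet, reserved
columns ``pellet_id, year, month, area, plant_fraction``, and one column per
prey taxon holding the integer count.  A *long* dialect
(``pellet_id, year, month, area, plant_fraction, taxon, count``) and an XLSX
reader (for deposited supplementary workbooks, with a configurable column
mapping) are also provided.  All text output is UTF-8 CSV with RFC-4180
quoting (pandas defaults); parsing is locale-independent (decimal point).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .datamodel import (
    AvailabilityDataset,
    AvailabilitySample,
    PelletDataset,
    PelletRecord,
    PreyTaxon,
    TraitTable,
)

logger = logging.getLogger("pelletdiet")

PELLET_RESERVED = ("pellet_id", "year", "month", "area", "plant_fraction")
AVAIL_RESERVED = ("sample_id", "year", "month", "area")

_TRAIT_COLUMNS = (
    "name",
    "shape_model",
    "mean_length_mm",
    "mean_width_mm",
    "fixed_volume_cm3",
    "mass_a",
    "mass_b",
    "group_mean_mass_mg",
    "is_vertebrate_or_carrion",
    "volume_overestimate",
)


class SchemaError(ValueError):
    """A mandatory column is missing or malformed."""


class ValidationError(ValueError):
    """A row violates a data-model invariant."""


def _read_table(path, dialect: str, column_map: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    path = Path(path)
    if dialect == "xlsx":
        df = pd.read_excel(path)
    elif str(path).endswith((".tsv", ".tab")):
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    return df


def _require(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing mandatory column(s) {missing}")


def _coerce_count(value, row_id: str, taxon: str) -> int:
    if pd.isna(value):
        return 0
    c = float(value)
    if c < 0:
        raise ValidationError(f"row {row_id!r}: negative count {value!r} for taxon {taxon!r}")
    if c != int(c):
        raise ValidationError(f"row {row_id!r}: non-integer count {value!r} for taxon {taxon!r}")
    return int(c)


def load_pellet_table(
    path,
    dialect: str = "wide_csv",
    column_map: Optional[Mapping[str, str]] = None,
    taxa: Optional[Sequence[str]] = None,
) -> PelletDataset:
    """Load a pellet-level prey-count table.

    ``dialect`` is one of ``wide_csv`` (canonical), ``long_csv`` or ``xlsx``
    (wide layout inside a workbook; ``column_map`` renames workbook columns
    onto the canonical schema).  Row order is preserved; counts are coerced
    to integers; unknown reserved-adjacent columns are kept in
    ``dataset.metadata['extra_columns']``.
    """
    if dialect not in ("wide_csv", "long_csv", "xlsx"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_table(path, dialect, column_map)
    if df.empty:
        raise ValidationError(f"{path}: no pellets in table")

    if dialect == "long_csv":
        _require(df, PELLET_RESERVED[:4] + ("taxon", "count"), "pellet table (long)")
        records = []
        taxon_order: dict[str, None] = {}
        for pid, sub in df.groupby("pellet_id", sort=False):
            first = sub.iloc[0]
            counts = {}
            for _, row in sub.iterrows():
                t = str(row["taxon"])
                taxon_order.setdefault(t)
                counts[t] = counts.get(t, 0) + _coerce_count(row["count"], str(pid), t)
            pf = float(first["plant_fraction"]) if "plant_fraction" in sub.columns else 0.0
            records.append(
                PelletRecord(
                    pellet_id=str(pid),
                    year=int(first["year"]),
                    month=int(first["month"]),
                    area=str(first["area"]),
                    counts=counts,
                    plant_fraction=pf,
                )
            )
        taxa = tuple(taxa) if taxa is not None else tuple(taxon_order)
        ds = PelletDataset(records, taxa)
    else:
        _require(df, PELLET_RESERVED, "pellet table")
        taxon_cols = [c for c in df.columns if c not in PELLET_RESERVED]
        if taxa is not None:
            extra = [c for c in taxon_cols if c not in set(taxa)]
            taxon_cols = [c for c in taxon_cols if c in set(taxa)]
        else:
            extra = []
        records = []
        for _, row in df.iterrows():
            pid = str(row["pellet_id"])
            counts = {t: _coerce_count(row[t], pid, t) for t in taxon_cols}
            records.append(
                PelletRecord(
                    pellet_id=pid,
                    year=int(row["year"]),
                    month=int(row["month"]),
                    area=str(row["area"]),
                    counts=counts,
                    plant_fraction=float(row["plant_fraction"]),
                )
            )
        ds = PelletDataset(records, tuple(taxa) if taxa is not None else tuple(taxon_cols))
        if extra:
            ds.metadata["extra_columns"] = df[["pellet_id"] + extra]

    bad = [(r.pellet_id, p) for r in ds.records for p in r.check()]
    if bad:
        rid, msg = bad[0]
        raise ValidationError(f"{path}: pellet {rid!r}: {msg} ({len(bad)} problem(s) total)")
    logger.info("loaded %d pellets, %d taxa from %s", len(ds), len(ds.taxa), path)
    return ds


def write_pellet_table(dataset: PelletDataset, path) -> None:
    """Write the canonical wide CSV (or TSV if the suffix says so)."""
    df = dataset.to_frame()
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, index=False, sep=sep)


def load_availability_table(
    path,
    dialect: str = "wide_csv",
    column_map: Optional[Mapping[str, str]] = None,
    taxa: Optional[Sequence[str]] = None,
) -> AvailabilityDataset:
    """Load a biocenometer availability table (wide layout, no plant fraction)."""
    if dialect not in ("wide_csv", "xlsx"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_table(path, dialect, column_map)
    if df.empty:
        raise ValidationError(f"{path}: no samples in availability table")
    _require(df, AVAIL_RESERVED, "availability table")
    taxon_cols = [c for c in df.columns if c not in AVAIL_RESERVED]
    records = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        counts = {t: _coerce_count(row[t], sid, t) for t in taxon_cols}
        records.append(
            AvailabilitySample(
                sample_id=sid,
                year=int(row["year"]),
                month=int(row["month"]),
                area=str(row["area"]),
                counts=counts,
            )
        )
    ds = AvailabilityDataset(records, tuple(taxa) if taxa is not None else tuple(taxon_cols))
    logger.info("loaded %d availability samples, %d taxa from %s", len(ds), len(ds.taxa), path)
    return ds


def write_availability_table(dataset: AvailabilityDataset, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    dataset.to_frame().to_csv(path, index=False, sep=sep)


def load_trait_table(path) -> TraitTable:
    """Load per-taxon traits (shape model, dimensions, allometry, fallbacks)."""
    df = _read_table(path, "wide_csv")
    _require(df, ("name", "shape_model"), "trait table")

    def _opt(row, col):
        if col not in row or pd.isna(row[col]):
            return None
        return float(row[col])

    taxa = []
    for _, row in df.iterrows():
        a, b = _opt(row, "mass_a"), _opt(row, "mass_b")
        if (a is None) != (b is None):
            raise SchemaError(f"taxon {row['name']!r}: mass_a and mass_b must come together")
        shape = str(row["shape_model"])
        fixed = _opt(row, "fixed_volume_cm3")
        if shape == "fixed_displacement" and fixed is None:
            raise SchemaError(
                f"taxon {row['name']!r}: fixed_displacement requires fixed_volume_cm3"
            )
        taxa.append(
            PreyTaxon(
                name=str(row["name"]),
                shape_model=shape,
                mean_length=_opt(row, "mean_length_mm"),
                mean_width=_opt(row, "mean_width_mm"),
                fixed_volume=fixed,
                mass_regression=(a, b) if a is not None else None,
                group_mean_mass=_opt(row, "group_mean_mass_mg"),
                is_vertebrate_or_carrion=bool(row.get("is_vertebrate_or_carrion", False)),
                volume_overestimate=bool(row.get("volume_overestimate", False)),
            )
        )
    table = TraitTable(taxa)
    logger.info("loaded %d trait rows from %s", len(table), path)
    return table


def write_trait_table(traits: TraitTable, path) -> None:
    rows = []
    for t in traits:
        a, b = (t.mass_regression or (None, None))
        rows.append(
            {
                "name": t.name,
                "shape_model": t.shape_model,
                "mean_length_mm": t.mean_length,
                "mean_width_mm": t.mean_width,
                "fixed_volume_cm3": t.fixed_volume,
                "mass_a": a,
                "mass_b": b,
                "group_mean_mass_mg": t.group_mean_mass,
                "is_vertebrate_or_carrion": t.is_vertebrate_or_carrion,
                "volume_overestimate": t.volume_overestimate,
            }
        )
    pd.DataFrame(rows, columns=_TRAIT_COLUMNS).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML run configuration (taxon list, area labels, dialects...)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    return cfg
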