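"""Core data model for faecal-pellet diet studies.

The study design this package serves is a long-term scat survey: each faecal
pellet is one sampling unit carrying covariates (year, month, area), integer
prey counts per taxon, and a visually estimated plant (vegetal-matter)
fraction.  Prey availability is censused separately with a biocenometer — a
bottomless 1 m mesh cube dropped over a plot — giving per-taxon invertebrate
counts per area and date.  Per-taxon trait tables parameterise the geometric
volume models and the dry-mass allometries used for the volumetric and
biomass diet representations.

Units are fixed globally: lengths and widths in mm, volumes in cm³ and dry
masses in mg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "DEFAULT_AREAS",
    "SHAPE_MODELS",
    "PelletRecord",
    "AvailabilitySample",
    "PreyTaxon",
    "PelletDataset",
    "AvailabilityDataset",
    "TraitTable",
    "ValidationReport",
]

#: The five sampling areas of the original island survey; loaders accept any
#: label set, this is only the default universe used for validation.
DEFAULT_AREAS: tuple[str, ...] = ("High", "Low", "North", "West", "Jetty")

SHAPE_MODELS = ("prolate_spheroid", "cylinder", "fixed_displacement")


@dataclass(frozen=True)
class PelletRecord:
    """One faecal pellet: covariates, per-taxon prey counts, plant fraction.

    ``measurements`` optionally carries per-item (taxon, length mm, width mm)
    triples for items that were measurable; they refer to a subset of the
    counted items and feed the per-item biomass pathway.
    """

    pellet_id: str
    year: int
    month: int
    area: str
    counts: Mapping[str, int]
    plant_fraction: float = 0.0
    measurements: Optional[Sequence[tuple[str, float, float]]] = None

    def total_items(self) -> int:
        return int(sum(self.counts.values()))

    def check(self) -> list[str]:
        """Return a list of invariant-violation messages (empty if sound)."""
        problems = []
        if not 1 <= int(self.month) <= 12:
            problems.append(f"month {self.month} outside 1-12")
        if not 0.0 <= float(self.plant_fraction) <= 1.0:
            problems.append(f"plant_fraction {self.plant_fraction} outside [0,1]")
        for taxon, c in self.counts.items():
            if c < 0:
                problems.append(f"negative count {c} for taxon {taxon!r}")
        if self.total_items() == 0 and not self.plant_fraction > 0:
            problems.append("pellet has zero prey items and zero plant fraction")
        return problems


@dataclass(frozen=True)
class AvailabilitySample:
    """One biocenometer census: per-taxon invertebrate counts for a plot."""

    sample_id: str
    year: int
    month: int
    area: str
    counts: Mapping[str, int]

    def total_items(self) -> int:
        return int(sum(self.counts.values()))

    def check(self) -> list[str]:
        problems = []
        if not 1 <= int(self.month) <= 12:
            problems.append(f"month {self.month} outside 1-12")
        if not self.counts:
            problems.append("availability sample has no taxon entries")
        for taxon, c in self.counts.items():
            if c < 0:
                problems.append(f"negative count {c} for taxon {taxon!r}")
        return problems


@dataclass(frozen=True)
class PreyTaxon:
    """Per-taxon traits driving the volume and dry-mass estimators.

    Parameters
    ----------
    shape_model
        Geometric model used for the prey volume: ``prolate_spheroid``
        (ellipsoid of revolution of length L and width W), ``cylinder``
        (e.g. millipedes), or ``fixed_displacement`` (bulky taxa whose
        volume was measured once by displacement in alcohol).
    mass_regression
        Optional ``(a, b)`` pair of the dry-mass allometry m = a·L^b with m
        in mg and L in mm.
    group_mean_mass
        Mean dry mass (mg) recorded for the taxon, used when an item could
        be identified but not measured.
    volume_overestimate
        Annotation that the displacement volume overstates the ingested
        soft-part volume (snail shells, partially eaten crabs); carried into
        reports, never corrected.
    """

    name: str
    shape_model: str = "prolate_spheroid"
    mean_length: Optional[float] = None  # mm
    mean_width: Optional[float] = None  # mm
    fixed_volume: Optional[float] = None  # cm^3
    mass_regression: Optional[tuple[float, float]] = None  # (a mg·mm^-b, b)
    group_mean_mass: Optional[float] = None  # mg
    is_vertebrate_or_carrion: bool = False
    volume_overestimate: bool = False

    def __post_init__(self):
        if self.shape_model not in SHAPE_MODELS:
            raise ValueError(
                f"unknown shape model {self.shape_model!r} for taxon {self.name!r};"
                f" expected one of {SHAPE_MODELS}"
            )
        if self.shape_model == "fixed_displacement":
            if self.fixed_volume is None or not self.fixed_volume > 0:
                raise ValueError(
                    f"taxon {self.name!r}: fixed_displacement requires fixed_volume > 0"
                )
        if self.mass_regression is not None and not self.mass_regression[0] > 0:
            raise ValueError(f"taxon {self.name!r}: allometry coefficient a must be > 0")


def _union_taxa(records: Iterable, explicit: Optional[Sequence[str]]) -> tuple[str, ...]:
    if explicit is not None:
        return tuple(explicit)
    seen: dict[str, None] = {}
    for r in records:
        for t in r.counts:
            seen.setdefault(t)
    return tuple(seen)


@dataclass
class PelletDataset:
    """Ordered collection of pellet records plus the global taxon list."""

    records: list[PelletRecord]
    taxa: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.taxa = _union_taxa(self.records, self.taxa or None)
        ids = [r.pellet_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pellet_id values: {dupes[:5]}")
        for r in self.records:
            unknown = set(r.counts) - set(self.taxa)
            if unknown:
                raise ValueError(
                    f"pellet {r.pellet_id!r} counts taxa outside the taxon list: {sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def counts_matrix(self):
        """Pellets × taxa integer count matrix (numpy array)."""
        import numpy as np

        out = np.zeros((len(self.records), len(self.taxa)), dtype=np.int64)
        index = {t: j for j, t in enumerate(self.taxa)}
        for i, r in enumerate(self.records):
            for t, c in r.counts.items():
                out[i, index[t]] = c
        return out

    def to_frame(self):
        """Wide DataFrame: reserved covariate columns then one column per taxon."""
        import pandas as pd

        rows = []
        for r in self.records:
            row = {
                "pellet_id": r.pellet_id,
                "year": r.year,
                "month": r.month,
                "area": r.area,
                "plant_fraction": r.plant_fraction,
            }
            for t in self.taxa:
                row[t] = int(r.counts.get(t, 0))
            rows.append(row)
        return pd.DataFrame(rows)

    def subset(self, predicate) -> "PelletDataset":
        return PelletDataset(
            [r for r in self.records if predicate(r)], self.taxa, dict(self.metadata)
        )


@dataclass
class AvailabilityDataset:
    """Ordered collection of biocenometer samples plus the taxon list."""

    records: list[AvailabilitySample]
    taxa: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.taxa = _union_taxa(self.records, self.taxa or None)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def pooled_counts(self, average: bool = False) -> dict[str, float]:
        """Counts summed over samples (or averaged per sample if requested)."""
        total: dict[str, float] = {t: 0.0 for t in self.taxa}
        for r in self.records:
            for t, c in r.counts.items():
                total[t] += c
        if average and self.records:
            n = len(self.records)
            total = {t: c / n for t, c in total.items()}
        return total

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.records:
            row = {
                "sample_id": r.sample_id,
                "year": r.year,
                "month": r.month,
                "area": r.area,
            }
            for t in self.taxa:
                row[t] = int(r.counts.get(t, 0))
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class TraitTable:
    """Keyed collection of :class:`PreyTaxon` rows."""

    taxa: list[PreyTaxon]

    def __post_init__(self):
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate taxon names in trait table: {dupes}")
        self._by_name = {t.name: t for t in self.taxa}

    def __len__(self) -> int:
        return len(self.taxa)

    def __iter__(self):
        return iter(self.taxa)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def get(self, name: str) -> Optional[PreyTaxon]:
        return self._by_name.get(name)

    def __getitem__(self, name: str) -> PreyTaxon:
        return self._by_name[name]

    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.taxa)


@dataclass
class ValidationReport:
    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.errors

    def __bool__(self) -> bool:
        return self.is_valid

    def summary(self) -> str:
        lines = [f"valid: {self.is_valid}",
                 f"errors: {len(self.errors)}", f"warnings: {len(self.warnings)}"]
        for rid, msg in self.errors:
            lines.append(f"  ERROR [{rid}] {msg}")
        for rid, msg in self.warnings:
            lines.append(f"  WARN  [{rid}] {msg}")
        return "\n".join(lines)


def validate(
    dataset: PelletDataset | AvailabilityDataset,
    traits: Optional[TraitTable] = None,
    areas: Optional[Sequence[str]] = None,
) -> ValidationReport:
    """Validate a dataset against its invariants and (optionally) a trait table.

    Pure: never mutates its inputs.  Count taxa absent from the trait table
    are warnings, not errors — frequency metrics remain computable, only the
    volume/biomass pathways are blocked.
    """
    report = ValidationReport()
    area_universe = set(areas) if areas is not None else None
    for r in dataset.records:
        rid = getattr(r, "pellet_id", None) or getattr(r, "sample_id", "?")
        for msg in r.check():
            report.errors.append((rid, msg))
        if area_universe is not None and r.area not in area_universe:
            report.errors.append((rid, f"area {r.area!r} not in {sorted(area_universe)}"))
        if traits is not None:
            for t, c in r.counts.items():
                if c > 0 and t not in traits:
                    report.warnings.append(
                        (rid, f"taxon {t!r} absent from trait table; volume/biomass unavailable")
                    )
    return report
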