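"""Diet composition: the four standard representations of a pellet diet.

A diet table can be expressed by numbers (%n, share of total prey items), by
presence (%p, share of pellets containing the prey), by volume (%vol, share
of summed prey volume with taxon-mean volumes applied to the count table)
and by biomass (%b, share of estimated total dry mass).  The volume of an
item comes from a geometric model — prolate spheroid V = (4/3)π(L/2)(W/2)²,
cylinder V = π(W/2)²L, or a fixed displacement volume — and its dry mass
from a three-tier hierarchy: taxon allometry m = a·L^b on the measured
length, else the taxon's mean recorded mass, else the overall mean mass over
all groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import PelletDataset, PreyTaxon, TraitTable

__all__ = [
    "prey_volume",
    "prey_dry_mass",
    "CohortMeans",
    "DietSummary",
    "DietComposition",
    "DietCompositionResults",
    "diet_frequencies",
    "diet_volume_profile",
    "diet_biomass_profile",
]


class DimensionError(ValueError):
    """A required prey dimension is unavailable."""


class EstimationError(ValueError):
    """No rule of the mass hierarchy can fire."""


def prey_volume(
    taxon: PreyTaxon,
    length: Optional[float] = None,
    width: Optional[float] = None,
) -> float:
    """Volume of one prey item in cm³.

    ``length``/``width`` (mm) override the taxon means; for
    ``fixed_displacement`` taxa the stored displacement volume is returned
    regardless of dimensions.
    """
    if taxon.shape_model == "fixed_displacement":
        return float(taxon.fixed_volume)
    L = length if length is not None else taxon.mean_length
    W = width if width is not None else taxon.mean_width
    if L is None or W is None:
        raise DimensionError(
            f"taxon {taxon.name!r}: {taxon.shape_model} volume needs length and width"
        )
    if taxon.shape_model == "prolate_spheroid":
        mm3 = (4.0 / 3.0) * math.pi * (L / 2.0) * (W / 2.0) ** 2
    else:  # cylinder
        mm3 = math.pi * (W / 2.0) ** 2 * L
    return mm3 / 1000.0  # mm^3 -> cm^3


@dataclass(frozen=True)
class CohortMeans:
    """Fallback dry masses (mg): per identified group, and overall."""

    group_means: Mapping[str, float] = field(default_factory=dict)
    overall_mean: Optional[float] = None


def prey_dry_mass(
    taxon: Optional[PreyTaxon],
    length: Optional[float] = None,
    cohort_means: Optional[CohortMeans] = None,
) -> float:
    """Dry mass of one prey item in mg, by the three-tier hierarchy.

    1. allometry a·L^b when the taxon has a regression and the item a length;
    2. else the taxon's mean recorded mass (item identified, unmeasured);
    3. else the overall mean mass across all groups (unidentifiable remains,
       ``taxon`` None or without any mass information).
    Exactly one rule fires for any input.
    """
    if taxon is not None and taxon.mass_regression is not None and length is not None:
        a, b = taxon.mass_regression
        return a * length**b
    if taxon is not None:
        gm = taxon.group_mean_mass
        if gm is None and cohort_means is not None:
            gm = cohort_means.group_means.get(taxon.name)
        if gm is not None:
            return float(gm)
    if cohort_means is not None and cohort_means.overall_mean is not None:
        return float(cohort_means.overall_mean)
    name = taxon.name if taxon is not None else "<unidentified>"
    raise EstimationError(f"taxon {name!r}: no regression, no mean mass available")


@dataclass
class DietSummary:
    """Per-group diet composition in the four representations.

    Percentages are on 0–100 scales; each filled vector sums to 100 over the
    taxa with defined values.  ``plant_presence_pct`` is the percentage of
    pellets in the group with a positive plant fraction.
    """

    group_key: tuple
    n_pellets: int
    n_items: int
    pct_numeric: dict[str, float] = field(default_factory=dict)
    pct_presence: dict[str, float] = field(default_factory=dict)
    pct_volume: dict[str, float] = field(default_factory=dict)
    pct_biomass: dict[str, float] = field(default_factory=dict)
    plant_presence_pct: float = float("nan")
    flags: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        taxa = list(self.pct_numeric) or list(self.pct_presence)
        rows = []
        for t in taxa:
            rows.append(
                {
                    "taxon": t,
                    "pct_numeric": self.pct_numeric.get(t, float("nan")),
                    "pct_presence": self.pct_presence.get(t, float("nan")),
                    "pct_volume": self.pct_volume.get(t, float("nan")),
                    "pct_biomass": self.pct_biomass.get(t, float("nan")),
                }
            )
        df = pd.DataFrame(rows)
        for name, value in zip(_group_names_of(self.group_key), self.group_key):
            df.insert(0, name, value)
        return df


def _group_names_of(key: tuple) -> list[str]:
    return [f"g{i}" for i in range(len(key))]


class DietComposition:
    """Model object: diet composition of a pellet dataset by group.

    Parameters
    ----------
    dataset
        Pellet dataset.
    traits
        Trait table; required for the volume and biomass representations.
    group_by
        Covariate names (subset of ``year, month, area``) defining the
        groups; ``None`` pools everything into one group.
    cohort_means
        Fallback masses for the biomass hierarchy; when omitted, per-taxon
        ``group_mean_mass`` entries from the trait table are used and the
        overall mean is their count-weighted average.
    """

    def __init__(
        self,
        dataset: PelletDataset,
        traits: Optional[TraitTable] = None,
        group_by: Optional[Sequence[str]] = None,
        cohort_means: Optional[CohortMeans] = None,
    ):
        if len(dataset) == 0:
            raise ValueError("empty dataset")
        self.dataset = dataset
        self.traits = traits
        self.group_by = tuple(group_by) if group_by else ()
        self.cohort_means = cohort_means

    # -- grouping ---------------------------------------------------------
    def _groups(self) -> list[tuple[tuple, list]]:
        if not self.group_by:
            return [((), list(self.dataset.records))]
        buckets: dict[tuple, list] = {}
        for r in self.dataset.records:
            key = tuple(getattr(r, g) for g in self.group_by)
            buckets.setdefault(key, []).append(r)
        return sorted(buckets.items(), key=lambda kv: tuple(map(str, kv[0])))

    def _default_cohort_means(self) -> CohortMeans:
        if self.cohort_means is not None:
            return self.cohort_means
        gm = {}
        if self.traits is not None:
            gm = {
                t.name: t.group_mean_mass
                for t in self.traits
                if t.group_mean_mass is not None
            }
        overall = float(np.mean(list(gm.values()))) if gm else None
        return CohortMeans(group_means=gm, overall_mean=overall)

    # -- fitting ----------------------------------------------------------
    def fit(self) -> "DietCompositionResults":
        taxa = self.dataset.taxa
        cohort = self._default_cohort_means()
        summaries = []
        for key, records in self._groups():
            totals = {t: 0 for t in taxa}
            present = {t: 0 for t in taxa}
            plant_present = 0
            for r in records:
                for t, c in r.counts.items():
                    totals[t] += c
                    if c > 0:
                        present[t] += 1
                if r.plant_fraction > 0:
                    plant_present += 1
            n_items = sum(totals.values())
            n_pellets = len(records)
            s = DietSummary(
                group_key=key,
                n_pellets=n_pellets,
                n_items=n_items,
                plant_presence_pct=100.0 * plant_present / n_pellets,
            )
            if n_items > 0:
                s.pct_numeric = {t: 100.0 * totals[t] / n_items for t in taxa}
            else:
                s.flags["pct_numeric"] = "undefined: group has zero prey items"
            s.pct_presence = {t: 100.0 * present[t] / n_pellets for t in taxa}

            if self.traits is not None and n_items > 0:
                s.pct_volume = self._volume_pct(totals)
                s.pct_biomass = self._biomass_pct(records, totals, cohort)
                for t in taxa:
                    tr = self.traits.get(t)
                    if tr is not None and tr.volume_overestimate and totals[t] > 0:
                        s.flags[t] = "volume_overestimate"
            summaries.append(s)
        return DietCompositionResults(self, summaries)

    def _volume_pct(self, totals: Mapping[str, int]) -> dict[str, float]:
        # taxon-mean volumes applied to the count table, deliberately not
        # per-item measurements (the volumetric pathway mirrors frequency
        # tables scaled by average volumes)
        vols = {}
        for t, c in totals.items():
            if c == 0:
                vols[t] = 0.0
                continue
            tr = self.traits.get(t)
            if tr is None:
                raise DimensionError(f"taxon {t!r} counted but absent from trait table")
            vols[t] = c * prey_volume(tr)
        total = sum(vols.values())
        if total <= 0:
            return {}
        return {t: 100.0 * v / total for t, v in vols.items()}

    def _biomass_pct(
        self, records, totals: Mapping[str, int], cohort: CohortMeans
    ) -> dict[str, float]:
        mass = {t: 0.0 for t in totals}
        measured = {t: 0 for t in totals}
        for r in records:
            for t, L, _w in r.measurements or ():
                tr = self.traits.get(t)
                mass[t] += prey_dry_mass(tr, length=L, cohort_means=cohort)
                measured[t] += 1
        for t, c in totals.items():
            unmeasured = c - measured[t]
            if unmeasured < 0:
                raise ValueError(f"taxon {t!r}: more measurements than counted items")
            if unmeasured:
                tr = self.traits.get(t)
                mass[t] += unmeasured * prey_dry_mass(tr, cohort_means=cohort)
        total = sum(mass.values())
        if total <= 0:
            return {}
        return {t: 100.0 * m / total for t, m in mass.items()}


class DietCompositionResults:
    """Fitted composition tables; one :class:`DietSummary` per group."""

    def __init__(self, model: DietComposition, summaries: list[DietSummary]):
        self.model = model
        self.summaries = summaries

    def __iter__(self):
        return iter(self.summaries)

    def __len__(self):
        return len(self.summaries)

    def summary(self) -> pd.DataFrame:
        """Long table: one row per (group, taxon) with n, %n, %p, %vol, %b."""
        rows = []
        names = list(self.model.group_by) or []
        for s in self.summaries:
            for t in self.model.dataset.taxa:
                row = dict(zip(names, s.group_key))
                row.update(
                    taxon=t,
                    n_pellets=s.n_pellets,
                    n_items=s.n_items,
                    pct_numeric=s.pct_numeric.get(t, float("nan")),
                    pct_presence=s.pct_presence.get(t, float("nan")),
                    pct_volume=s.pct_volume.get(t, float("nan")),
                    pct_biomass=s.pct_biomass.get(t, float("nan")),
                    plant_presence_pct=s.plant_presence_pct,
                    flag=s.flags.get(t, ""),
                )
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)


# -- thin functional façade over the model object -------------------------

def diet_frequencies(
    dataset: PelletDataset, group_by: Optional[Sequence[str]] = None
) -> list[DietSummary]:
    """%n and %p per group (no traits needed)."""
    return list(DietComposition(dataset, group_by=group_by).fit())


def diet_volume_profile(
    dataset: PelletDataset, traits: TraitTable, group_by: Optional[Sequence[str]] = None
) -> list[DietSummary]:
    """Full summaries including %vol (and %b) per group."""
    return list(DietComposition(dataset, traits=traits, group_by=group_by).fit())


def diet_biomass_profile(
    dataset: PelletDataset,
    traits: TraitTable,
    group_by: Optional[Sequence[str]] = None,
    cohort_means: Optional[CohortMeans] = None,
) -> list[DietSummary]:
    return list(
        DietComposition(
            dataset, traits=traits, group_by=group_by, cohort_means=cohort_means
        ).fit()
    )
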