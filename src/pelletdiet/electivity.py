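"""Electivity: prey preference relative to environmental availability.

Two indices on the [−1, +1] scale, where −1 is total avoidance, 0 random
selection and +1 maximum positive selection:

* Ivlev's selectivity index as modified by Jacobs,
  ``D = (r − p) / (r + p − 2 r p)``, with ``r`` the proportion of the prey
  in the diet and ``p`` its proportion in the environment; and
* the Vanderploeg–Scavia electivity ``E* = (W − 1/n) / (W + 1/n)`` with the
  selectivity coefficient ``W_i = (r_i/p_i) / Σ_j (r_j/p_j)`` and ``n`` the
  number of available prey types — better behaved at small sample sizes.

Degenerate taxa (absent from the diet, the availability sample, or both)
are flagged rather than silently dropped: availability censuses only see
epigeal and flying prey, so absence flags carry real information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .composition import DietSummary
from .datamodel import AvailabilityDataset

__all__ = [
    "jacobs_D",
    "vanderploeg_scavia",
    "electivity_profile",
    "Electivity",
    "ElectivityTable",
]

FLAG_OK = "ok"
FLAG_BOTH = "absent_in_both"
FLAG_AVAIL = "absent_in_availability"
FLAG_DIET = "absent_in_diet"


def jacobs_D(r, p):
    """Ivlev–Jacobs selectivity D = (r−p)/(r+p−2rp); NaN when r = p = 0.

    Accepts scalars or arrays; antisymmetric under swap of ``r`` and ``p``.
    """
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    denom = r + p - 2.0 * r * p
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom == 0.0, np.nan, (r - p) / np.where(denom == 0, 1.0, denom))
    # within [0,1]^2 the denominator vanishes only at (0,0) and (1,1);
    # (1,1) has limit 0 (no selection), (0,0) is genuinely undefined
    out = np.where((r == 1) & (p == 1), 0.0, out)
    out = np.clip(out, -1.0, 1.0)  # guard float round-off at the boundaries
    out = np.where((r == 0) & (p == 0), np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def vanderploeg_scavia(
    r_vec: Sequence[float], p_vec: Sequence[float], n_types: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Selectivity coefficients W and electivities E* for aligned r, p vectors.

    ``n_types`` defaults to the number of available prey types (p > 0).  W is
    normalised over taxa with p > 0 (finite ratios); a taxon eaten but absent
    from the availability sample has an infinite ratio, and its E* is the
    +1 limit.  A taxon with r = 0 has W = 0 and E* = −1.
    """
    r = np.asarray(r_vec, dtype=float)
    p = np.asarray(p_vec, dtype=float)
    if r.shape != p.shape or r.ndim != 1:
        raise ValueError("r and p must be aligned 1-D vectors")
    if r.size < 2:
        raise ValueError("need at least two prey types")
    if not np.any(p > 0):
        raise ValueError("all availability proportions are zero")

    finite = p > 0
    ratio = np.zeros_like(r)
    ratio[finite] = r[finite] / p[finite]
    total = ratio[finite].sum()
    W = np.full_like(r, np.nan)
    if total > 0:
        W[finite] = ratio[finite] / total
    else:  # diet entirely outside the availability universe
        W[finite] = 0.0
    n = int(n_types) if n_types is not None else int(finite.sum())
    inv_n = 1.0 / n
    with np.errstate(invalid="ignore"):
        E = (W - inv_n) / (W + inv_n)
    E[~finite & (r > 0)] = 1.0  # limit of W -> inf
    E[~finite & (r == 0)] = np.nan
    return W, E


@dataclass
class ElectivityTable:
    """Per-taxon electivity results over a shared taxon universe."""

    frame: pd.DataFrame  # columns: taxon, r, p, W, D, E_star, flag
    n_types: int
    universe: str

    def summary(self) -> pd.DataFrame:
        return self.frame.copy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __getitem__(self, taxon: str) -> pd.Series:
        sub = self.frame[self.frame["taxon"] == taxon]
        if sub.empty:
            raise KeyError(taxon)
        return sub.iloc[0]


class Electivity:
    """Model object joining a diet to an availability sample.

    Parameters
    ----------
    diet
        A :class:`~pelletdiet.composition.DietSummary` (its %n vector is
        used) or a plain taxon → count/percentage mapping.
    availability
        An :class:`~pelletdiet.datamodel.AvailabilityDataset` (counts pooled
        over samples by default; per-replicate averaging by option) or a
        taxon → count mapping.
    universe
        ``"union"`` (default): all taxa seen in either table;
        ``"availability_taxa"``: restrict to availability taxa.
    """

    def __init__(
        self,
        diet: Union[DietSummary, Mapping[str, float]],
        availability: Union[AvailabilityDataset, Mapping[str, float]],
        universe: str = "union",
        average_replicates: bool = False,
    ):
        if universe not in ("union", "availability_taxa"):
            raise ValueError(f"unknown universe {universe!r}")
        self.universe = universe
        if isinstance(diet, DietSummary):
            self.diet_weights = {t: v for t, v in diet.pct_numeric.items()}
        else:
            self.diet_weights = dict(diet)
        if isinstance(availability, AvailabilityDataset):
            self.avail_weights = availability.pooled_counts(average=average_replicates)
        else:
            self.avail_weights = dict(availability)

    def fit(self) -> ElectivityTable:
        diet_taxa = [t for t, v in self.diet_weights.items() if v > 0]
        avail_taxa = [t for t, v in self.avail_weights.items() if v > 0]
        if not set(diet_taxa) & set(avail_taxa):
            raise ValueError("diet and availability share no taxa")
        if self.universe == "availability_taxa":
            taxa = list(dict.fromkeys(list(self.avail_weights)))
        else:
            taxa = list(dict.fromkeys(list(self.diet_weights) + list(self.avail_weights)))

        r_raw = np.array([max(self.diet_weights.get(t, 0.0), 0.0) for t in taxa])
        p_raw = np.array([max(self.avail_weights.get(t, 0.0), 0.0) for t in taxa])
        if r_raw.sum() <= 0 or p_raw.sum() <= 0:
            raise ValueError("diet or availability has zero total weight on the universe")
        r = r_raw / r_raw.sum()
        p = p_raw / p_raw.sum()

        D = jacobs_D(r, p)
        W, E = vanderploeg_scavia(r, p)
        flags = []
        for ri, pi in zip(r, p):
            if ri == 0 and pi == 0:
                flags.append(FLAG_BOTH)
            elif pi == 0:
                flags.append(FLAG_AVAIL)
            elif ri == 0:
                flags.append(FLAG_DIET)
            else:
                flags.append(FLAG_OK)
        frame = pd.DataFrame(
            {
                "taxon": taxa,
                "r": r,
                "p": p,
                "W": W,
                "D": D,
                "E_star": E,
                "flag": flags,
            }
        )
        n = int((p > 0).sum())
        return ElectivityTable(frame=frame, n_types=n, universe=self.universe)


def electivity_profile(
    diet: Union[DietSummary, Mapping[str, float]],
    availability: Union[AvailabilityDataset, Mapping[str, float]],
    universe: str = "union",
    average_replicates: bool = False,
) -> ElectivityTable:
    """Functional façade over :class:`Electivity`."""
    return Electivity(diet, availability, universe, average_replicates).fit()
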