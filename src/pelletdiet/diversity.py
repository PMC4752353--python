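"""Hill-number ("true") diversity and bootstrap Tukey-like group contrasts.

Rather than comparing raw indices on incommensurable scales, diversity is
expressed as Hill numbers: for relative abundances ``p_i`` and order ``q``,

    ^qD = (Σ p_i^q)^(1/(1−q)),   ^1D = exp(−Σ p_i ln p_i)  (the q→1 limit).

^0D is species richness, ^1D the exponential of Shannon entropy, and ^2D the
inverse of the Simpson concentration λ = Σ p_i².  The default order grid is
the integral orders −1..3; negative orders up-weight rare categories, so
zero-count categories are always excluded.

Group comparisons are all-pairs ("Tukey-like") contrasts whose reference
distribution comes from a pellet-level bootstrap: pellets are resampled with
replacement within each group, counts re-pooled, and the Hill-number
difference recomputed per replicate.  Two-tailed p-values come from the
centred bootstrap distribution; the single-step max-modulus adjustment over
the studentised statistics controls the family-wise error across pairs
within each order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import PelletDataset

__all__ = [
    "hill_number",
    "simpson_with_variance",
    "diversity_profile",
    "DiversityProfile",
    "HillContrast",
    "HillContrastResults",
    "bootstrap_hill_contrasts",
]

DEFAULT_Q_GRID = (-1.0, 0.0, 1.0, 2.0, 3.0)
DEFAULT_Q_TESTS = (0.0, 1.0, 2.0)


def _hill_from_props(P: np.ndarray, q: float) -> np.ndarray:
    """Hill number along the last axis of a (stack of) probability vectors.

    Zero entries must already be masked out (they are handled by the callers
    via masked sums); P rows must each sum to 1 over their positive entries.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        if q == 1.0:
            logs = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), 0.0)
            return np.exp(-np.sum(P * logs, axis=-1))
        if q == 0.0:
            return np.sum(P > 0, axis=-1).astype(float)
        powed = np.where(P > 0, np.where(P > 0, P, 1.0) ** q, 0.0)
        s = np.sum(powed, axis=-1)
        return np.exp(np.log(s) / (1.0 - q))


def hill_number(counts: Sequence[float], q: float) -> float:
    """^qD of a non-negative count (or abundance) vector.

    Zero-count categories are excluded for every order — mandatory for
    q < 0, where they would otherwise contribute infinite weight.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero count vector has no diversity")
    p = c[c > 0] / total
    return float(_hill_from_props(p, float(q)))


def simpson_with_variance(counts: Sequence[float]) -> tuple[float, float, float]:
    """Simpson concentration λ = Σp̂², diversity 1−λ, and its variance.

    The variance is the classical large-sample estimator
    ``var = (4/N)(Σ p̂_i³ − (Σ p̂_i²)²)`` with N the total count.
    """
    c = np.asarray(counts, dtype=float)
    N = c.sum()
    if N < 2:
        raise ValueError("Simpson variance needs at least 2 items")
    p = c / N
    lam = float(np.sum(p**2))
    var = float(4.0 / N * (np.sum(p**3) - lam**2))
    return lam, 1.0 - lam, var


@dataclass
class DiversityProfile:
    """Hill numbers over an order grid for one group's pooled counts."""

    group_key: tuple
    q_grid: tuple[float, ...]
    hill: dict[float, float]
    simpson_concentration: float
    simpson_diversity: float
    simpson_variance: float
    n_items: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "q": list(self.q_grid),
                "hill": [self.hill[q] for q in self.q_grid],
            }
        )


def _grouped_counts(
    dataset: PelletDataset, group_by: Optional[Sequence[str]]
) -> list[tuple[tuple, np.ndarray]]:
    """(group key, pellets × taxa count matrix) pairs in sorted key order."""
    X = dataset.counts_matrix()
    if not group_by:
        return [((), X)]
    keys = [tuple(getattr(r, g) for g in group_by) for r in dataset.records]
    buckets: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        buckets.setdefault(k, []).append(i)
    return [
        (k, X[idx]) for k, idx in sorted(buckets.items(), key=lambda kv: tuple(map(str, kv[0])))
    ]


def diversity_profile(
    dataset: PelletDataset,
    group_by: Optional[Sequence[str]] = None,
    q_grid: Sequence[float] = DEFAULT_Q_GRID,
) -> list[DiversityProfile]:
    """Pool counts over pellets within each group and evaluate the profile.

    Groups with zero total count are skipped (with a warning logged).
    """
    import logging

    out = []
    for key, X in _grouped_counts(dataset, group_by):
        pooled = X.sum(axis=0)
        if pooled.sum() <= 0:
            logging.getLogger("pelletdiet").warning(
                "diversity_profile: group %r has zero prey items; skipped", key
            )
            continue
        lam, div, var = simpson_with_variance(pooled)
        out.append(
            DiversityProfile(
                group_key=key,
                q_grid=tuple(float(q) for q in q_grid),
                hill={float(q): hill_number(pooled, q) for q in q_grid},
                simpson_concentration=lam,
                simpson_diversity=div,
                simpson_variance=var,
                n_items=int(pooled.sum()),
            )
        )
    return out


@dataclass
class PairwiseDiversityTest:
    pair: tuple
    q: float
    observed_diff: float
    p_raw: float
    p_adjusted: float
    B: int
    seed: Optional[int]


class HillContrast:
    """Model object: all-pairs bootstrap contrasts of group Hill numbers.

    The resampling unit is the pellet (the independent sampling unit of a
    scat survey), resampled with replacement within its own group.
    """

    def __init__(
        self,
        dataset: PelletDataset,
        group_by: Sequence[str],
        q_set: Sequence[float] = DEFAULT_Q_TESTS,
    ):
        self.dataset = dataset
        self.group_by = tuple(group_by)
        self.q_set = tuple(float(q) for q in q_set)
        self.groups = _grouped_counts(dataset, self.group_by)
        if len(self.groups) < 2:
            raise ValueError("need at least two groups to contrast")
        for key, X in self.groups:
            if X.shape[0] < 2:
                raise ValueError(f"group {key!r} has a single pellet; cannot resample")
            if X.sum() <= 0:
                raise ValueError(f"group {key!r} has zero prey items")

    def fit(
        self,
        B: int = 5000,
        seed: Optional[int] = None,
        adjust: str = "max-modulus",
    ) -> "HillContrastResults":
        """Run ``B`` bootstrap replications (seeded) and assemble the tests.

        ``adjust`` is ``"max-modulus"`` (single-step, resampling-based) or
        ``"holm"``.
        """
        if adjust not in ("max-modulus", "holm"):
            raise ValueError(f"unknown adjustment {adjust!r}")
        rng = np.random.default_rng(seed)
        nq = len(self.q_set)
        G = len(self.groups)

        observed = np.empty((G, nq))
        boot = np.empty((G, B, nq))
        for g, (_key, X) in enumerate(self.groups):
            n = X.shape[0]
            pooled = X.sum(axis=0)
            for j, q in enumerate(self.q_set):
                observed[g, j] = hill_number(pooled, q)
            idx = rng.integers(0, n, size=(B, n))
            # B × taxa pooled counts per replicate
            pooled_b = X[idx].sum(axis=1).astype(float)
            totals = pooled_b.sum(axis=1, keepdims=True)
            P = np.where(pooled_b > 0, pooled_b / totals, 0.0)
            for j, q in enumerate(self.q_set):
                boot[g, :, j] = _hill_from_props(P, q)

        pairs = list(combinations(range(G), 2))
        tests: list[PairwiseDiversityTest] = []
        for j, q in enumerate(self.q_set):
            obs_d = np.array([observed[a, j] - observed[b, j] for a, b in pairs])
            boot_d = np.stack([boot[a, :, j] - boot[b, :, j] for a, b in pairs])  # pairs × B
            centred = boot_d - obs_d[:, None]
            sd = centred.std(axis=1, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)  # degenerate pair: all replicates equal
            t_obs = np.abs(obs_d) / sd
            t_boot = np.abs(centred) / sd[:, None]
            p_raw = (np.sum(t_boot >= t_obs[:, None], axis=1) + 1.0) / (B + 1.0)
            if adjust == "max-modulus":
                max_t = t_boot.max(axis=0)  # B
                p_adj = (np.sum(max_t[None, :] >= t_obs[:, None], axis=1) + 1.0) / (B + 1.0)
            else:
                p_adj = _holm(p_raw)
            for k, (a, b) in enumerate(pairs):
                tests.append(
                    PairwiseDiversityTest(
                        pair=(self.groups[a][0], self.groups[b][0]),
                        q=q,
                        observed_diff=float(obs_d[k]),
                        p_raw=float(p_raw[k]),
                        p_adjusted=float(max(p_adj[k], p_raw[k])),
                        B=B,
                        seed=seed,
                    )
                )
        return HillContrastResults(self, tests, B=B, seed=seed, adjust=adjust)


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


class HillContrastResults:
    def __init__(self, model, tests, B, seed, adjust):
        self.model = model
        self.tests = tests
        self.B = B
        self.seed = seed
        self.adjust = adjust

    def __iter__(self):
        return iter(self.tests)

    def summary(self) -> pd.DataFrame:
        rows = []
        for t in self.tests:
            rows.append(
                {
                    "group_a": "/".join(map(str, t.pair[0])),
                    "group_b": "/".join(map(str, t.pair[1])),
                    "q": t.q,
                    "diff": t.observed_diff,
                    "p_raw": t.p_raw,
                    "p_adj": t.p_adjusted,
                    "B": t.B,
                    "seed": t.seed,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)


def bootstrap_hill_contrasts(
    dataset: PelletDataset,
    group_by: Sequence[str],
    q_set: Sequence[float] = DEFAULT_Q_TESTS,
    B: int = 5000,
    seed: Optional[int] = None,
    adjust: str = "max-modulus",
) -> list[PairwiseDiversityTest]:
    """Functional façade over :class:`HillContrast`."""
    return list(HillContrast(dataset, group_by, q_set).fit(B=B, seed=seed, adjust=adjust))
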