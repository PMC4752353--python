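"""Classical frequency tests: G-test (with pairwise batteries), Fisher
exact, and Kruskal–Wallis.

The G-test is the log-likelihood-ratio goodness-of-fit / independence test
``G = 2 Σ O ln(O/E)`` over cells with positive observed count, referred to
the χ² distribution (df = k−1 for one-way tables against given or uniform
expectations, (r−1)(c−1) for two-way tables against independence).  No
continuity or Williams correction is applied by default; a Williams
correction is available by flag.

Fisher's exact test is two-sided by the common convention: the p-value sums
the probabilities of all tables (with the observed margins) whose
probability does not exceed the observed table's.  Tables larger than 2×2
are handled by seeded Monte-Carlo sampling from the fixed-margins null.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "FreqTestResult",
    "g_test",
    "pairwise_g_tests",
    "fisher_exact",
    "kruskal_wallis",
]


@dataclass(frozen=True)
class FreqTestResult:
    statistic: float
    df: Optional[int]
    pvalue: float
    method: str
    table_shape: tuple[int, ...]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "method": self.method,
                    "statistic": self.statistic,
                    "df": self.df,
                    "p": self.pvalue,
                    "shape": "x".join(map(str, self.table_shape)),
                }
            ]
        )


def _g_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    if np.any((expected == 0) & (observed > 0)):
        raise ValueError("expected cell is zero where observed is positive")
    mask = observed > 0
    return float(2.0 * np.sum(observed[mask] * np.log(observed[mask] / expected[mask])))


def g_test(
    observed,
    expected=None,
    williams: bool = False,
) -> FreqTestResult:
    """Log-likelihood-ratio (G) test for one-way or two-way count tables.

    One-way: expected defaults to uniform (or the supplied vector, rescaled
    to the observed total).  Two-way: expected defaults to the independence
    model from the margins.
    """
    O = np.asarray(observed, dtype=float)
    if np.any(O < 0):
        raise ValueError("counts must be non-negative")
    total = O.sum()
    if total <= 0:
        raise ValueError("table has zero total count")

    if O.ndim == 1:
        if expected is None:
            E = np.full_like(O, total / O.size)
        else:
            E = np.asarray(expected, dtype=float)
            E = E * (total / E.sum())
        df = O.size - 1
        G = _g_statistic(O, E)
        q = 1.0
        if williams:
            q = 1.0 + (O.size**2 - 1) / (6.0 * total * df)
    elif O.ndim == 2:
        if expected is None:
            E = np.outer(O.sum(axis=1), O.sum(axis=0)) / total
        else:
            E = np.asarray(expected, dtype=float)
        r, c = O.shape
        df = (r - 1) * (c - 1)
        G = _g_statistic(O, E)
        q = 1.0
        if williams:
            row_term = total * np.sum(1.0 / O.sum(axis=1)) - 1.0
            col_term = total * np.sum(1.0 / O.sum(axis=0)) - 1.0
            q = 1.0 + row_term * col_term / (6.0 * total * df)
    else:
        raise ValueError("observed must be 1-D or 2-D")

    G /= q
    p = float(stats.chi2.sf(G, df)) if df > 0 else 1.0
    method = "G-test" + (" (Williams)" if williams else "")
    return FreqTestResult(G, int(df), min(p, 1.0), method, O.shape)


def pairwise_g_tests(
    table,
    labels: Optional[Sequence] = None,
    adjust: Optional[str] = None,
    williams: bool = False,
) -> pd.DataFrame:
    """G-test every unordered pair of rows of a groups × categories table.

    Returns a symmetric p-value matrix (diagonal NaN).  ``adjust="holm"``
    applies a Holm correction across the battery; raw p by default.
    """
    if isinstance(table, pd.DataFrame):
        O = table.to_numpy(dtype=float)
        labels = list(table.index) if labels is None else list(labels)
    else:
        O = np.asarray(table, dtype=float)
        labels = list(range(O.shape[0])) if labels is None else list(labels)
    k = O.shape[0]
    if k < 2:
        raise ValueError("need at least two groups")
    pairs = list(combinations(range(k), 2))
    pvals = []
    for i, j in pairs:
        sub = O[[i, j]]
        keep = sub.sum(axis=0) > 0  # drop categories empty in both rows
        pvals.append(g_test(sub[:, keep], williams=williams).pvalue)
    pvals = np.asarray(pvals)
    if adjust == "holm":
        order = np.argsort(pvals)
        adj = np.empty_like(pvals)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (len(pvals) - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        pvals = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    M = np.full((k, k), np.nan)
    for (i, j), p in zip(pairs, pvals):
        M[i, j] = M[j, i] = p
    return pd.DataFrame(M, index=labels, columns=labels)


def _log_table_prob(table: np.ndarray) -> float:
    """Log probability of an r×c table under the fixed-margins null."""
    n = table.sum()
    return float(
        gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def fisher_exact(
    table,
    mc_reps: int = 10000,
    seed: Optional[int] = None,
) -> FreqTestResult:
    """Fisher's exact test; 2×2 exact, larger tables by Monte Carlo.

    The two-sided p sums probabilities of tables at most as probable as the
    observed one.  Monte-Carlo p uses the (count+1)/(reps+1) estimator and
    is reproducible from ``seed``.
    """
    O = np.asarray(table, dtype=float)
    if O.ndim != 2:
        raise ValueError("table must be 2-D")
    if np.any(O < 0) or np.any(O != np.round(O)):
        raise ValueError("table must hold non-negative integers")
    O = O.astype(np.int64)
    if np.any(O.sum(axis=1) == 0) or np.any(O.sum(axis=0) == 0):
        import warnings

        warnings.warn("degenerate margins: a row or column is empty; p = 1")
        return FreqTestResult(float("nan"), None, 1.0, "Fisher exact", O.shape)

    if O.shape == (2, 2):
        _, p = stats.fisher_exact(O, alternative="two-sided")
        return FreqTestResult(float("nan"), None, float(p), "Fisher exact", O.shape)

    # Monte-Carlo with fixed margins: shuffle item labels and re-cross-tab
    rng = np.random.default_rng(seed)
    log_obs = _log_table_prob(O)
    rows = np.repeat(np.arange(O.shape[0]), O.sum(axis=1))
    cols = np.repeat(np.arange(O.shape[1]), O.sum(axis=0))
    hits = 0
    tol = 1e-9
    for _ in range(mc_reps):
        perm = rng.permutation(cols)
        t = np.zeros(O.shape, dtype=np.int64)
        np.add.at(t, (rows, perm), 1)
        if _log_table_prob(t) <= log_obs + tol:
            hits += 1
    p = (hits + 1.0) / (mc_reps + 1.0)
    return FreqTestResult(float("nan"), None, float(p), "Fisher exact (MC)", O.shape)


def kruskal_wallis(*samples) -> FreqTestResult:
    """Kruskal–Wallis rank test with tie correction; χ² reference, df = k−1."""
    if len(samples) == 1 and hasattr(samples[0], "__iter__") and hasattr(
        next(iter(samples[0]), None), "__iter__"
    ):
        samples = tuple(samples[0])
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    flat = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    if flat.size < 3:
        raise ValueError("need at least 3 observations in total")
    df = len(samples) - 1
    if np.all(flat == flat[0]):
        return FreqTestResult(0.0, df, 1.0, "Kruskal-Wallis", (len(samples),))
    H, p = stats.kruskal(*samples)
    return FreqTestResult(float(H), df, float(p), "Kruskal-Wallis", (len(samples),))
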