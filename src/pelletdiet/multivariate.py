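"""Permutational multivariate tests on distance matrices.

Two companion procedures for community (diet-composition) tables:

* **PERMANOVA** — partitions the total sum of squared interpoint distances
  over the terms of a crossed factorial design (sequential, order-dependent
  sums of squares on the Gower-centred inner-product matrix), forms a
  pseudo-F for each term against the residual, and assesses it by free
  permutation of observation labels:
  ``p = (#{F_perm >= F_obs} + 1) / (n_perm + 1)``.
* **Multivariate dispersion homogeneity** — the multivariate analogue of
  Levene's test: observations are embedded by principal-coordinate analysis
  (negative eigenvalues retained with their sign), each observation's
  distance to its own group centroid is computed with the negative-axis
  correction, and the one-way F on those distances is assessed by permuting
  the distances among groups.

The default distance for per-pellet count tables is Bray–Curtis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "bray_curtis_matrix",
    "distance_matrix",
    "Permanova",
    "PermanovaResults",
    "BetaDispersion",
    "BetaDispersionResults",
    "permanova",
    "dispersion_test",
]

_EPS = 1e-10


def bray_curtis_matrix(X) -> np.ndarray:
    """Symmetric Bray–Curtis distance matrix of a pellets × taxa count table.

    ``d_ij = Σ|x_i − x_j| / Σ(x_i + x_j)`` ∈ [0, 1].  Rows with zero total
    have no defined dissimilarity and must be excluded beforehand.
    """
    X = np.asarray(X, dtype=float)
    sums = X.sum(axis=1)
    if np.any(sums <= 0):
        bad = np.flatnonzero(sums <= 0)
        raise ValueError(
            f"rows {bad.tolist()[:10]} have zero total count; exclude empty pellets first"
        )
    return squareform(pdist(X, metric="braycurtis"))


def distance_matrix(X, metric: str = "braycurtis") -> np.ndarray:
    """Distance matrix with the package's supported metrics."""
    if metric in ("braycurtis", "bray", "bray_curtis"):
        return bray_curtis_matrix(X)
    if metric == "euclidean":
        return squareform(pdist(np.asarray(X, dtype=float), metric="euclidean"))
    if metric == "jaccard":
        B = (np.asarray(X) > 0).astype(float)
        return squareform(pdist(B, metric="jaccard"))
    raise ValueError(f"unsupported distance metric {metric!r}")


def _gower_center(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _parse_formula(formula: str) -> list[tuple[str, ...]]:
    """Expand a crossed-factor formula ('year*month*area', 'a+b', 'a:b')."""
    terms: list[tuple[str, ...]] = []

    def add(t: tuple[str, ...]):
        if t not in terms:
            terms.append(t)

    for chunk in formula.replace(" ", "").split("+"):
        if not chunk:
            continue
        if "*" in chunk:
            factors = chunk.split("*")
            from itertools import combinations

            for order in range(1, len(factors) + 1):
                for combo in combinations(factors, order):
                    add(tuple(combo))
        elif ":" in chunk:
            add(tuple(chunk.split(":")))
        else:
            add((chunk,))
    if not terms:
        raise ValueError(f"formula {formula!r} names no terms")
    return terms


def _term_dummies(design: pd.DataFrame, term: tuple[str, ...]) -> np.ndarray:
    missing = [f for f in term if f not in design.columns]
    if missing:
        raise ValueError(f"design is missing factor column(s) {missing}")
    key = design[list(term)].astype(str).agg(":".join, axis=1)
    return pd.get_dummies(key, dtype=float).to_numpy()


def _orthonormal_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal column basis of X (rank-revealing, SVD-based)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    return U[:, s > tol]


@dataclass
class PermanovaTerm:
    name: str
    df: int
    ss: float
    pseudo_F: float
    r_squared: float
    p_perm: float


class Permanova:
    """PERMANOVA model: a distance matrix plus a factorial design.

    Parameters
    ----------
    distance
        Square symmetric distance matrix, or a pellets × taxa count table
        (then ``metric`` is applied; empty rows must be excluded).
    design
        DataFrame of factor columns aligned with the rows of ``distance``.
        All factors are treated as categorical.
    formula
        Right-hand-side formula over design columns, e.g. ``"year*month*area"``.
        Sums of squares are sequential in the expanded term order, which is
        user-visible in the results.
    """

    def __init__(
        self,
        distance,
        design: pd.DataFrame,
        formula: str,
        metric: str = "braycurtis",
    ):
        D = np.asarray(distance, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
            D = distance_matrix(distance, metric)
        self.D = D
        n = D.shape[0]
        if len(design) != n:
            raise ValueError("design rows must align with the distance matrix")
        self.design = design.reset_index(drop=True)
        self.terms = _parse_formula(formula)
        self.formula = formula
        self.n = n

        self.G = _gower_center(D)
        self.total_ss = float(np.trace(self.G))
        if self.total_ss <= _EPS:
            raise ValueError("total sum of squares is zero: all observations identical")

        # cumulative orthonormal bases -> per-term projector increments
        ones = np.ones((n, 1))
        Q_prev = _orthonormal_basis(ones)
        H_prev = Q_prev @ Q_prev.T
        rank_prev = Q_prev.shape[1]
        X = ones
        self._increments: list[np.ndarray] = []
        self._dfs: list[int] = []
        for term in self.terms:
            X = np.hstack([X, _term_dummies(self.design, term)])
            Q = _orthonormal_basis(X)
            df = Q.shape[1] - rank_prev
            if df == 0:
                raise ValueError(
                    f"term {':'.join(term)!r} is aliased with earlier terms (df = 0)"
                )
            H = Q @ Q.T
            self._increments.append(H - H_prev)
            self._dfs.append(df)
            H_prev, rank_prev = H, Q.shape[1]
        self._residual_projector = np.eye(n) - H_prev
        self.df_residual = n - rank_prev

    def _ss_profile(self, G: np.ndarray) -> tuple[np.ndarray, float]:
        term_ss = np.array([float(np.sum(M * G)) for M in self._increments])
        resid_ss = float(np.sum(self._residual_projector * G))
        return term_ss, resid_ss

    def fit(
        self, n_perm: int = 9999, seed: Optional[int] = None, exact: bool = False
    ) -> "PermanovaResults":
        """Estimate permutation p-values with ``n_perm`` random permutations,
        or (``exact=True``) enumerate all n! permutations — feasible only for
        very small n; then p = #{F_perm >= F_obs} / n! with the identity
        permutation always counted, so p is never 0."""
        if self.df_residual <= 0:
            raise ValueError("no residual degrees of freedom; reduce the model")
        term_ss, resid_ss = self._ss_profile(self.G)
        dfs = np.array(self._dfs, dtype=float)
        F_obs = (term_ss / dfs) / (resid_ss / self.df_residual)

        def _F_of(perm) -> np.ndarray:
            Gp = self.G[np.ix_(perm, perm)]
            ss_p, resid_p = self._ss_profile(Gp)
            return (ss_p / dfs) / (resid_p / self.df_residual)

        tol = 1e-12
        if exact:
            from itertools import permutations as _perms
            from math import factorial

            if self.n > 9:
                raise ValueError("exact enumeration is limited to n <= 9")
            exceed = np.zeros(len(self.terms))
            for perm in _perms(range(self.n)):
                exceed += _F_of(list(perm)) >= F_obs - tol
            p = exceed / factorial(self.n)
            n_perm = factorial(self.n)
        else:
            rng = np.random.default_rng(seed)
            exceed = np.zeros(len(self.terms))
            for _ in range(n_perm):
                exceed += _F_of(rng.permutation(self.n)) >= F_obs - tol
            p = (exceed + 1.0) / (n_perm + 1.0)

        terms = [
            PermanovaTerm(
                name=":".join(t),
                df=int(self._dfs[i]),
                ss=float(term_ss[i]),
                pseudo_F=float(F_obs[i]),
                r_squared=float(term_ss[i] / self.total_ss),
                p_perm=float(p[i]),
            )
            for i, t in enumerate(self.terms)
        ]
        return PermanovaResults(
            self, terms, residual_ss=float(resid_ss), n_perm=n_perm, seed=seed
        )


class PermanovaResults:
    def __init__(self, model: Permanova, terms, residual_ss, n_perm, seed):
        self.model = model
        self.terms = terms
        self.residual_ss = residual_ss
        self.residual_df = model.df_residual
        self.total_ss = model.total_ss
        self.n_perm = n_perm
        self.seed = seed

    def term(self, name: str) -> PermanovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "term": t.name,
                "df": t.df,
                "ss": t.ss,
                "pseudo_F": t.pseudo_F,
                "R2": t.r_squared,
                "p_perm": t.p_perm,
            }
            for t in self.terms
        ]
        rows.append(
            {
                "term": "Residual",
                "df": self.residual_df,
                "ss": self.residual_ss,
                "pseudo_F": float("nan"),
                "R2": self.residual_ss / self.total_ss,
                "p_perm": float("nan"),
            }
        )
        rows.append(
            {
                "term": "Total",
                "df": sum(t.df for t in self.terms) + self.residual_df,
                "ss": self.total_ss,
                "pseudo_F": float("nan"),
                "R2": 1.0,
                "p_perm": float("nan"),
            }
        )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)


class BetaDispersion:
    """Multivariate dispersion homogeneity (Levene-analogue) model.

    Observations are embedded by principal coordinates of the distance
    matrix; axes with negative eigenvalues are retained and subtract from
    squared distances (floored at zero) when measuring each observation's
    distance to its own group centroid.
    """

    def __init__(self, distance, groups: Sequence, metric: str = "braycurtis"):
        D = np.asarray(distance, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
            D = distance_matrix(distance, metric)
        self.D = D
        self.groups = np.asarray([str(g) for g in groups])
        if len(self.groups) != D.shape[0]:
            raise ValueError("groups must align with the distance matrix")
        self.levels, self.codes = np.unique(self.groups, return_inverse=True)
        if len(self.levels) < 2:
            raise ValueError("need at least two groups")
        sizes = np.bincount(self.codes)
        if np.any(sizes < 2):
            small = self.levels[sizes < 2]
            raise ValueError(f"group(s) {small.tolist()} have fewer than 2 observations")

        G = _gower_center(D)
        lam, V = np.linalg.eigh(G)
        keep = np.abs(lam) > max(np.abs(lam).max(), 1.0) * 1e-10
        lam, V = lam[keep], V[:, keep]
        pos, neg = lam > 0, lam < 0
        self._coords_pos = V[:, pos] * np.sqrt(lam[pos])
        self._coords_neg = V[:, neg] * np.sqrt(-lam[neg])
        self.centroid_distances = self._distances_to_centroids()

    def _distances_to_centroids(self) -> np.ndarray:
        z2 = np.zeros(len(self.groups))
        for code in range(len(self.levels)):
            idx = self.codes == code
            cp = self._coords_pos[idx].mean(axis=0)
            cn = self._coords_neg[idx].mean(axis=0)
            d2 = ((self._coords_pos[idx] - cp) ** 2).sum(axis=1) - (
                (self._coords_neg[idx] - cn) ** 2
            ).sum(axis=1)
            z2[idx] = np.maximum(d2, 0.0)
        return np.sqrt(z2)

    @staticmethod
    def _anova_F(z: np.ndarray, codes: np.ndarray, k: int) -> float:
        n = len(z)
        grand = z.mean()
        ssb = 0.0
        ssw = 0.0
        for code in range(k):
            zi = z[codes == code]
            ssb += len(zi) * (zi.mean() - grand) ** 2
            ssw += ((zi - zi.mean()) ** 2).sum()
        if ssw <= 0:
            return np.inf if ssb > 0 else 0.0
        return (ssb / (k - 1)) / (ssw / (n - k))

    def fit(self, n_perm: int = 9999, seed: Optional[int] = None) -> "BetaDispersionResults":
        z = self.centroid_distances
        k = len(self.levels)
        F_obs = self._anova_F(z, self.codes, k)
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            zp = rng.permutation(z)
            if self._anova_F(zp, self.codes, k) >= F_obs:
                exceed += 1
        p = (exceed + 1.0) / (n_perm + 1.0)
        per_group = pd.DataFrame(
            {
                "group": self.levels,
                "n": np.bincount(self.codes),
                "mean_distance": [z[self.codes == c].mean() for c in range(k)],
                "sd_distance": [z[self.codes == c].std(ddof=1) for c in range(k)],
            }
        )
        return BetaDispersionResults(
            self, F=float(F_obs), p_perm=float(p), per_group=per_group,
            n_perm=n_perm, seed=seed,
        )


class BetaDispersionResults:
    def __init__(self, model, F, p_perm, per_group, n_perm, seed):
        self.model = model
        self.F = F
        self.p_perm = p_perm
        self.per_group = per_group
        self.n_perm = n_perm
        self.seed = seed

    def summary(self) -> pd.DataFrame:
        df = self.per_group.copy()
        df["F"] = self.F
        df["p_perm"] = self.p_perm
        df["n_perm"] = self.n_perm
        df["seed"] = self.seed
        return df

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)


def permanova(
    distance,
    design: pd.DataFrame,
    formula: str,
    n_perm: int = 9999,
    seed: Optional[int] = None,
    metric: str = "braycurtis",
) -> PermanovaResults:
    """Functional façade over :class:`Permanova`."""
    return Permanova(distance, design, formula, metric).fit(n_perm=n_perm, seed=seed)


def dispersion_test(
    distance,
    groups: Sequence,
    n_perm: int = 9999,
    seed: Optional[int] = None,
    metric: str = "braycurtis",
) -> BetaDispersionResults:
    """Functional façade over :class:`BetaDispersion`."""
    return BetaDispersion(distance, groups, metric).fit(n_perm=n_perm, seed=seed)
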