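"""PERMANOVA and dispersion homogeneity against classical, enumerated and
external (vegan, scikit-bio) oracles."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pelletdiet.multivariate import (
    BetaDispersion,
    Permanova,
    bray_curtis_matrix,
    distance_matrix,
)


def _fixture_18x5():
    """Deterministic 18-pellet × 5-taxon count table with a 2×3 design."""
    rng = np.random.default_rng(42)
    X = rng.integers(0, 9, size=(18, 5)) + (rng.random((18, 5)) < 0.3)
    X = np.asarray(X, dtype=int)
    X[X.sum(1) == 0, 0] = 1
    year = np.repeat([2009, 2011], 9)
    area = np.tile(np.repeat(["H", "L", "N"], 3), 2)
    return X, pd.DataFrame({"year": year, "area": area})


class TestBrayCurtis:
    def test_disjoint_compositions(self):
        D = bray_curtis_matrix([[1, 0], [0, 1]])
        assert D[0, 1] == pytest.approx(1.0)

    def test_identical_rows(self):
        D = bray_curtis_matrix([[2, 3], [2, 3]])
        assert D[0, 1] == pytest.approx(0.0)

    def test_hand_value(self):
        D = bray_curtis_matrix([[2, 1], [1, 1]])
        assert D[0, 1] == pytest.approx(0.2)

    def test_zero_row_instructs_exclusion(self):
        with pytest.raises(ValueError, match="exclude"):
            bray_curtis_matrix([[0, 0], [1, 2]])

    def test_bounds_and_symmetry(self, rng):
        X = rng.integers(0, 10, size=(12, 6)) + 1
        D = bray_curtis_matrix(X)
        assert np.allclose(D, D.T) and np.all((D >= 0) & (D <= 1))
        assert np.all(np.diag(D) == 0)


class TestPermanova:
    def test_univariate_euclidean_equals_classical_anova(self, rng):
        y = rng.normal(size=15)
        groups = np.repeat(["a", "b", "c"], 5)
        res = Permanova(
            y[:, None], pd.DataFrame({"g": groups}), "g", metric="euclidean"
        ).fit(n_perm=99, seed=0)
        F_classical = stats.f_oneway(*(y[groups == g] for g in "abc")).statistic
        assert res.terms[0].pseudo_F == pytest.approx(F_classical, rel=1e-10)

    def test_exact_permutation_p_matches_independent_enumeration(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=6)
        groups = np.array(["a", "a", "a", "b", "b", "b"])

        def anova_F(values):
            return stats.f_oneway(values[groups == "a"], values[groups == "b"]).statistic

        F_obs = anova_F(y)
        count = sum(
            anova_F(y[list(p)]) >= F_obs - 1e-12 for p in permutations(range(6))
        )
        p_oracle = count / 720

        res = Permanova(
            y[:, None], pd.DataFrame({"g": groups}), "g", metric="euclidean"
        ).fit(exact=True)
        assert res.terms[0].p_perm == pytest.approx(p_oracle, abs=1e-12)

    def test_all_identical_observations_flagged(self):
        X = np.ones((6, 3))
        with pytest.raises(ValueError, match="identical"):
            Permanova(X, pd.DataFrame({"g": list("aabbcc")}), "g", metric="euclidean")

    def test_matches_frozen_vegan_adonis2_values(self):
        # oracle: vegan 2.7 adonis2(dist ~ year*area, by="terms") on the
        # deterministic fixture, Bray-Curtis
        X, design = _fixture_18x5()
        res = Permanova(X, design, "year*area").fit(n_perm=49, seed=0)
        expect = {
            "year": (1, 0.090009048620, 1.47906, 0.082562091437),
            "area": (2, 0.040685385141, 0.33428, 0.037319253339),
            "year:area": (2, 0.229235443443, 1.88343, 0.210269499928),
        }
        for name, (df, ss, F, r2) in expect.items():
            t = res.term(name)
            assert t.df == df
            assert t.ss == pytest.approx(ss, rel=1e-9)
            assert t.pseudo_F == pytest.approx(F, rel=1e-5)
            assert t.r_squared == pytest.approx(r2, rel=1e-9)
        assert res.residual_df == 12
        assert res.residual_ss == pytest.approx(0.730268385131, rel=1e-9)
        assert res.total_ss == pytest.approx(1.090198262336, rel=1e-9)

    def test_one_way_pseudo_F_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        X, design = _fixture_18x5()
        D = bray_curtis_matrix(X)
        mine = Permanova(D, design, "area").fit(n_perm=9, seed=0)
        theirs = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(D), design["area"].to_numpy(), permutations=9
        )
        assert mine.terms[0].pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_ss_partition_and_df_sum(self):
        X, design = _fixture_18x5()
        res = Permanova(X, design, "year*area").fit(n_perm=9, seed=0)
        parts = sum(t.ss for t in res.terms) + res.residual_ss
        assert parts == pytest.approx(res.total_ss, abs=1e-9)
        assert sum(t.df for t in res.terms) + res.residual_df == len(design) - 1

    def test_ss_invariant_to_seed_and_p_in_range(self):
        X, design = _fixture_18x5()
        r1 = Permanova(X, design, "year+area").fit(n_perm=99, seed=1)
        r2 = Permanova(X, design, "year+area").fit(n_perm=99, seed=2)
        for a, b in zip(r1.terms, r2.terms):
            assert a.ss == b.ss and a.pseudo_F == b.pseudo_F
            assert 0 < a.p_perm <= 1

    def test_reordering_observations_with_design_is_invariant(self):
        X, design = _fixture_18x5()
        perm = np.random.default_rng(3).permutation(len(design))
        r1 = Permanova(X, design, "year*area").fit(n_perm=9, seed=0)
        r2 = Permanova(
            X[perm], design.iloc[perm].reset_index(drop=True), "year*area"
        ).fit(n_perm=9, seed=0)
        for a, b in zip(r1.terms, r2.terms):
            assert a.ss == pytest.approx(b.ss, rel=1e-9)
            assert a.pseudo_F == pytest.approx(b.pseudo_F, rel=1e-9)

    def test_aliased_term_is_named(self):
        X, design = _fixture_18x5()
        design = design.assign(copy=design["area"])
        with pytest.raises(ValueError, match="copy"):
            Permanova(X, design, "area+copy")

    def test_jaccard_metric_available(self):
        X, design = _fixture_18x5()
        D = distance_matrix(X, "jaccard")
        assert np.all((D >= 0) & (D <= 1))


class TestBetaDispersion:
    def test_hand_example_distances(self):
        # 1-D points: group A at (0, 2), group B at (0, 4)
        pts = np.array([[0.0], [2.0], [0.0], [4.0]])
        bd = BetaDispersion(pts, ["A", "A", "B", "B"], metric="euclidean")
        assert bd.centroid_distances == pytest.approx([1.0, 1.0, 2.0, 2.0], abs=1e-9)
        res = bd.fit(n_perm=99, seed=0)
        # within-group distances are constant: SSW = 0, F diverges
        assert np.isinf(res.F)

    def test_coincident_group_has_zero_distances(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [0.0, 0.0], [2.0, 3.0]])
        bd = BetaDispersion(pts, ["A", "A", "B", "B"], metric="euclidean")
        assert bd.centroid_distances[:2] == pytest.approx([0.0, 0.0], abs=1e-9)

    def test_matches_frozen_vegan_betadisper_values(self):
        # oracle: vegan betadisper(type="centroid") + anova on the fixture
        X, design = _fixture_18x5()
        bd = BetaDispersion(X, design["area"])
        expect = [
            0.238237314808, 0.405426346374, 0.151189988591, 0.154556486113,
            0.219451370029, 0.168584381083, 0.189605479242, 0.290785834414,
            0.359067497200, 0.107320637763, 0.169660030540, 0.315703567860,
            0.159431242074, 0.348660760302, 0.236641338171, 0.103205172602,
            0.204338275056, 0.245489951971,
        ]
        assert bd.centroid_distances == pytest.approx(expect, abs=1e-9)
        res = bd.fit(n_perm=99, seed=0)
        assert res.F == pytest.approx(0.0681, abs=1e-4)

    def test_group_of_one_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            BetaDispersion(np.eye(3), ["A", "A", "B"], metric="euclidean")

    def test_null_p_is_not_extreme(self, rng):
        X = rng.integers(1, 10, size=(20, 4))
        groups = ["A"] * 10 + ["B"] * 10
        res = BetaDispersion(X, groups).fit(n_perm=199, seed=0)
        assert 0 < res.p_perm <= 1
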