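"""Volume and dry-mass estimators and the four diet representations."""

import math

import numpy as np
import pytest

from pelletdiet import (
    CohortMeans,
    DietComposition,
    PelletDataset,
    PelletRecord,
    PreyTaxon,
    TraitTable,
    diet_frequencies,
    prey_dry_mass,
    prey_volume,
)
from pelletdiet.composition import DimensionError, EstimationError


class TestPreyVolume:
    def test_prolate_spheroid_hand_value(self):
        taxon = PreyTaxon("x", "prolate_spheroid", mean_length=10, mean_width=4)
        # (4/3)π(L/2)(W/2)² = (4/3)π·5·4 mm³
        assert prey_volume(taxon) == pytest.approx(83.7758040957278 / 1000.0, rel=1e-12)

    def test_cylinder_hand_value(self):
        taxon = PreyTaxon("Diplopoda", "cylinder", mean_length=20, mean_width=3)
        assert prey_volume(taxon) == pytest.approx(math.pi * 1.5**2 * 20 / 1000.0, rel=1e-12)
        assert prey_volume(taxon) == pytest.approx(0.141372, abs=1e-6)

    def test_fixed_displacement_identity(self):
        taxon = PreyTaxon("Isopoda", "fixed_displacement", fixed_volume=1.25)
        assert prey_volume(taxon) == 1.25

    def test_measurement_overrides_means(self):
        taxon = PreyTaxon("x", "prolate_spheroid", mean_length=10, mean_width=4)
        assert prey_volume(taxon, length=20, width=4) == pytest.approx(2 * prey_volume(taxon))

    def test_missing_dimension_names_taxon(self):
        taxon = PreyTaxon("Araneae", "prolate_spheroid")
        with pytest.raises(DimensionError, match="Araneae"):
            prey_volume(taxon)


class TestPreyDryMass:
    means = CohortMeans(group_means={"y": 4.2}, overall_mean=3.1)

    def test_allometry_hand_value(self):
        taxon = PreyTaxon("x", mass_regression=(0.05, 2.5))
        assert prey_dry_mass(taxon, length=10) == pytest.approx(0.05 * 10**2.5, rel=1e-12)
        assert prey_dry_mass(taxon, length=10) == pytest.approx(15.811, abs=1e-3)

    def test_fallback_group_mean(self):
        taxon = PreyTaxon("y")
        assert prey_dry_mass(taxon, cohort_means=self.means) == pytest.approx(4.2)

    def test_fallback_overall_mean_for_unidentified(self):
        assert prey_dry_mass(None, cohort_means=self.means) == pytest.approx(3.1)

    def test_hierarchy_precedence_is_total(self):
        # regression + length beats group mean beats overall mean
        taxon = PreyTaxon("y", mass_regression=(0.05, 2.5), group_mean_mass=99.0)
        assert prey_dry_mass(taxon, length=10, cohort_means=self.means) == pytest.approx(
            0.05 * 10**2.5
        )
        assert prey_dry_mass(taxon, cohort_means=self.means) == pytest.approx(99.0)

    def test_no_rule_fires_is_error(self):
        with pytest.raises(EstimationError):
            prey_dry_mass(PreyTaxon("z"))


class TestFrequencies:
    def test_toy_hand_counts(self, toy_pellets):
        (s,) = diet_frequencies(toy_pellets)
        assert s.n_pellets == 2 and s.n_items == 6
        assert s.pct_numeric == {"ants": pytest.approx(50.0), "beetles": pytest.approx(50.0)}
        assert s.pct_presence == {"ants": pytest.approx(50.0), "beetles": pytest.approx(100.0)}
        assert s.plant_presence_pct == pytest.approx(50.0)

    def test_single_pellet_single_taxon(self):
        ds = PelletDataset([PelletRecord("p", 2009, 5, "High", {"ants": 7})])
        (s,) = diet_frequencies(ds)
        assert s.pct_numeric["ants"] == 100.0 and s.pct_presence["ants"] == 100.0

    def test_group_keys_are_distinct_covariate_combinations(self):
        records = [
            PelletRecord(f"p{i}", y, m, a, {"ants": 1})
            for i, (y, m, a) in enumerate(
                [(2009, 5, "High"), (2009, 5, "High"), (2009, 6, "Low"), (2011, 5, "High")]
            )
        ]
        res = diet_frequencies(PelletDataset(records), group_by=["year", "month", "area"])
        assert {s.group_key for s in res} == {(2009, 5, "High"), (2009, 6, "Low"), (2011, 5, "High")}

    def test_zero_prey_group_flagged(self):
        ds = PelletDataset([PelletRecord("p", 2009, 5, "High", {"ants": 0}, 0.5)])
        (s,) = diet_frequencies(ds)
        assert not s.pct_numeric and "pct_numeric" in s.flags


def _two_taxon_dataset(c1, c2):
    return PelletDataset(
        [PelletRecord("p1", 2009, 5, "High", {"a": c1, "b": c2})], ("a", "b")
    )


def _traits(v1, v2):
    # fixed volumes keep the %vol arithmetic transparent
    return TraitTable(
        [
            PreyTaxon("a", "fixed_displacement", fixed_volume=v1, group_mean_mass=1.0),
            PreyTaxon("b", "fixed_displacement", fixed_volume=v2, group_mean_mass=1.0),
        ]
    )


class TestVolumeProfile:
    def test_hand_arithmetic(self):
        res = DietComposition(_two_taxon_dataset(10, 10), traits=_traits(0.1, 0.3)).fit()
        s = res.summaries[0]
        assert s.pct_volume["a"] == pytest.approx(25.0)
        assert s.pct_volume["b"] == pytest.approx(75.0)

    def test_equal_volumes_reduce_to_frequencies(self):
        res = DietComposition(_two_taxon_dataset(3, 9), traits=_traits(0.2, 0.2)).fit()
        s = res.summaries[0]
        assert s.pct_volume == pytest.approx(s.pct_numeric)

    def test_single_taxon_is_100(self):
        res = DietComposition(_two_taxon_dataset(5, 0), traits=_traits(0.1, 0.3)).fit()
        assert res.summaries[0].pct_volume["a"] == pytest.approx(100.0)

    def test_volume_monotonicity(self):
        lo = DietComposition(_two_taxon_dataset(4, 6), traits=_traits(0.1, 0.3)).fit()
        hi = DietComposition(_two_taxon_dataset(4, 6), traits=_traits(0.2, 0.3)).fit()
        assert hi.summaries[0].pct_volume["a"] > lo.summaries[0].pct_volume["a"]
        assert hi.summaries[0].pct_volume["b"] < lo.summaries[0].pct_volume["b"]

    def test_counted_taxon_missing_from_traits_errors(self):
        ds = _two_taxon_dataset(1, 1)
        traits = TraitTable([PreyTaxon("a", "fixed_displacement", fixed_volume=0.1)])
        with pytest.raises(DimensionError, match="'b'"):
            DietComposition(ds, traits=traits).fit()


class TestBiomassProfile:
    def test_hand_arithmetic_with_measurement(self):
        ds = PelletDataset(
            [
                PelletRecord(
                    "p1", 2009, 5, "High", {"a": 1, "b": 1},
                    measurements=[("a", 10.0, 2.0)],
                )
            ],
            ("a", "b"),
        )
        traits = TraitTable(
            [
                PreyTaxon("a", "fixed_displacement", fixed_volume=0.1,
                          mass_regression=(0.05, 2.5), group_mean_mass=2.0),
                PreyTaxon("b", "fixed_displacement", fixed_volume=0.1, group_mean_mass=4.2),
            ]
        )
        s = DietComposition(ds, traits=traits).fit().summaries[0]
        m_a, m_b = 0.05 * 10**2.5, 4.2
        assert s.pct_biomass["a"] == pytest.approx(100 * m_a / (m_a + m_b), abs=1e-9)
        assert s.pct_biomass["a"] == pytest.approx(79.0, abs=0.1)
        assert s.pct_biomass["b"] == pytest.approx(21.0, abs=0.1)

    def test_all_items_one_taxon(self):
        s = DietComposition(_two_taxon_dataset(4, 0), traits=_traits(0.1, 0.1)).fit().summaries[0]
        assert s.pct_biomass["a"] == pytest.approx(100.0)

    def test_measured_at_mean_length_equals_fallback_path(self):
        traits = TraitTable(
            [
                PreyTaxon("a", "prolate_spheroid", mean_length=10.0, mean_width=2.0,
                          mass_regression=(0.05, 2.5),
                          group_mean_mass=0.05 * 10**2.5),
                PreyTaxon("b", "prolate_spheroid", mean_length=5.0, mean_width=1.0,
                          group_mean_mass=4.2),
            ]
        )
        measured = PelletDataset(
            [PelletRecord("p1", 2009, 5, "High", {"a": 1, "b": 1},
                          measurements=[("a", 10.0, 2.0)])],
            ("a", "b"),
        )
        fallback = PelletDataset(
            [PelletRecord("p1", 2009, 5, "High", {"a": 1, "b": 1})], ("a", "b")
        )
        s_m = DietComposition(measured, traits=traits).fit().summaries[0]
        s_f = DietComposition(fallback, traits=traits).fit().summaries[0]
        assert s_m.pct_biomass == pytest.approx(s_f.pct_biomass)


class TestInvariants:
    def test_percentages_sum_to_100(self, rng):
        from pelletdiet import default_trait_table

        taxa = default_trait_table().names()[:6]
        records = []
        for i in range(40):
            counts = dict(zip(taxa, rng.integers(0, 5, size=6)))
            if sum(counts.values()) == 0:
                counts[taxa[0]] = 1
            records.append(PelletRecord(f"p{i}", 2009, 5 + (i % 2), "High", counts))
        ds = PelletDataset(records, taxa)
        res = DietComposition(ds, traits=default_trait_table(), group_by=["month"]).fit()
        for s in res:
            for vec in (s.pct_numeric, s.pct_volume, s.pct_biomass):
                assert sum(vec.values()) == pytest.approx(100.0, abs=1e-9)

    def test_numeric_invariant_to_order_and_splitting_presence_not(self, toy_pellets):
        reordered = PelletDataset(list(reversed(toy_pellets.records)), toy_pellets.taxa)
        (orig,) = diet_frequencies(toy_pellets)
        (rev,) = diet_frequencies(reordered)
        assert orig.pct_numeric == pytest.approx(rev.pct_numeric)

        # split pellet p1 (ants 3, beetles 1) into two pellets
        split = PelletDataset(
            [
                PelletRecord("p1a", 2009, 5, "High", {"ants": 3, "beetles": 0}, 0.1),
                PelletRecord("p1b", 2009, 5, "High", {"ants": 0, "beetles": 1}, 0.1),
                toy_pellets.records[1],
            ],
            toy_pellets.taxa,
        )
        (sp,) = diet_frequencies(split)
        assert sp.pct_numeric == pytest.approx(orig.pct_numeric)  # %n invariant
        assert sp.pct_presence != pytest.approx(orig.pct_presence)  # %p is not

    def test_volume_overestimate_flag_carried(self):
        ds = _two_taxon_dataset(1, 1)
        traits = TraitTable(
            [
                PreyTaxon("a", "fixed_displacement", fixed_volume=1.2,
                          group_mean_mass=1.0, volume_overestimate=True),
                PreyTaxon("b", "fixed_displacement", fixed_volume=0.1, group_mean_mass=1.0),
            ]
        )
        s = DietComposition(ds, traits=traits).fit().summaries[0]
        assert s.flags.get("a") == "volume_overestimate" and "b" not in s.flags
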