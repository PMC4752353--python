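import numpy as np
import pytest

from pelletdiet import (
    AvailabilityDataset,
    AvailabilitySample,
    PelletDataset,
    PelletRecord,
    PreyTaxon,
    TraitTable,
)


@pytest.fixture
def toy_pellets() -> PelletDataset:
    """Two pellets over {ants, beetles}: counts (3,1) and (0,2)."""
    return PelletDataset(
        [
            PelletRecord("p1", 2009, 5, "High", {"ants": 3, "beetles": 1}, 0.1),
            PelletRecord("p2", 2009, 5, "High", {"ants": 0, "beetles": 2}, 0.0),
        ],
        ("ants", "beetles"),
    )


@pytest.fixture
def toy_traits() -> TraitTable:
    return TraitTable(
        [
            PreyTaxon("ants", "prolate_spheroid", mean_length=4.0, mean_width=1.0,
                      mass_regression=(0.05, 2.5), group_mean_mass=1.0),
            PreyTaxon("beetles", "prolate_spheroid", mean_length=8.0, mean_width=3.0,
                      group_mean_mass=4.2),
        ]
    )


@pytest.fixture
def toy_availability() -> AvailabilityDataset:
    return AvailabilityDataset(
        [
            AvailabilitySample("a1", 2009, 5, "High", {"ants": 15, "beetles": 35}),
            AvailabilitySample("a2", 2009, 5, "High", {"ants": 10, "beetles": 40}),
        ],
        ("ants", "beetles"),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
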