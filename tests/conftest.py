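import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hostmicrobe import (
    AbundanceTable,
    GenotypeMatrix,
    SimulationConfig,
    VariantRecord,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def two_pop_config():
    """Two balanced Balding-Nichols populations, no relatives, no zeros."""
    return SimulationConfig(
        n_donors=100,
        n_variants=2000,
        n_populations=2,
        fst=0.1,
        population_weights=(0.5, 0.5),
        related_pairs=(),
        n_species=40,
        n_pathways=30,
        zero_inflation=0.0,
        seed=101,
    )


@pytest.fixture(scope="session")
def two_pop_cohort(two_pop_config):
    return simulate_cohort(two_pop_config)


@pytest.fixture
def toy_genotypes():
    """A hand-sized genotype matrix: 4 donors x 5 variants, one missing call."""
    dosages = np.array(
        [
            [0.0, 1.0, 2.0, 1.0, 0.0],
            [2.0, 1.0, 0.0, 1.0, 0.0],
            [1.0, 0.0, 1.0, 2.0, np.nan],
            [1.0, 2.0, 1.0, 0.0, 0.0],
        ]
    )
    variants = [
        VariantRecord("chrS", 100 * (i + 1), f"v{i}") for i in range(5)
    ]
    return GenotypeMatrix(["a", "b", "c", "d"], variants, dosages)


@pytest.fixture
def replicate_table():
    """3 donors with 1, 2, and 3 replicate samples over 2 species."""
    values = pd.DataFrame(
        {
            "sp1": [0.2, 0.2, 0.4, 0.1, 0.2, 0.3],
            "sp2": [0.8, 0.8, 0.6, 0.9, 0.8, 0.7],
        },
        index=["s1", "s2", "s3", "s4", "s5", "s6"],
    )
    donor_of = {"s1": "d1", "s2": "d2", "s3": "d2", "s4": "d3", "s5": "d3",
                "s6": "d3"}
    return AbundanceTable(values, donor_of, "stool", kind="species")
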