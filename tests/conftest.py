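import numpy as np
import pytest

from commfba.community import build_community
from commfba.io import AbundanceTable
from commfba.simulate import (
    SimulationConfig,
    fermenter_model,
    make_cohort,
    make_species_models,
    producer_model,
)


@pytest.fixture
def s1():
    """Toy butyrate producer: glucose uptake capped at 10, 1:1 biomass:butyrate."""
    return producer_model("S1", 10.0)


@pytest.fixture
def s2():
    """Toy non-producer consuming the same glucose pool."""
    return fermenter_model("S2", 10.0)


@pytest.fixture
def s1_community(s1):
    return build_community([(s1, 1.0)], sample_id="toy")


@pytest.fixture
def small_registry():
    return make_species_models(8, fraction_producers=0.5, seed=11)


@pytest.fixture
def small_cohort_config():
    """Scaled-down two-visit cohort for fast integration tests."""
    return SimulationConfig(
        n_responders=8,
        n_nonresponders=5,
        v2_retained_responders=7,
        v2_retained_nonresponders=4,
        n_species=8,
        producer_enrichment_delta=0.3,
        seed=17,
    )


@pytest.fixture
def small_cohort(small_cohort_config, small_registry):
    return make_cohort(small_cohort_config, small_registry)


def random_abundance_table(rng: np.random.Generator, sample_id: str, taxa: list[str]):
    weights = rng.dirichlet(np.ones(len(taxa)))
    return AbundanceTable.from_entries(
        [(sample_id, t, float(w)) for t, w in zip(taxa, weights)]
    )
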