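import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mirseed as ms

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: One seed for every stochastic fixture so the suite is reproducible.
SEED = 20260929


@pytest.fixture(scope="session")
def repression_scenario() -> ms.Scenario:
    """Default planted-repression study: miR-96 planted in 30% of 2,000 genes."""
    return ms.simulate_scenario(ms.SynthConfig(seed=SEED))


@pytest.fixture(scope="session")
def repression_universe(repression_scenario) -> ms.SeedUniverse:
    return ms.build_universe(repression_scenario.utrs, repression_scenario.mirnas)


@pytest.fixture(scope="session")
def repression_partition(repression_scenario) -> ms.Partition:
    return ms.partition(repression_scenario.de_records, ms.Thresholds())


@pytest.fixture(scope="session")
def repression_enrichment(repression_partition, repression_universe):
    return ms.enrich_all(repression_partition, repression_universe)


@pytest.fixture(scope="session")
def repression_landscape(repression_scenario):
    scenario = repression_scenario
    panel = ms.mirna_word_panel(scenario.mirnas)
    index = ms.count_words(scenario.utrs, 7, panel)
    ranked = ms.RankedGenes.from_records(scenario.de_records)
    return ms.landscape(ranked, index, words=panel)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)
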