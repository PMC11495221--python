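import numpy as np
import pytest

import gmnet as g


@pytest.fixture(scope="session")
def structured_volume():
    """One community-structured volume plus its ground truth."""
    spec = g.VolumeSimSpec(shape=(24, 24, 24), n_communities=4,
                           community_signal=3.0, noise_sd=0.05, seed=42)
    vol, truth = g.simulate_volume(spec)
    return vol, truth


@pytest.fixture(scope="session")
def null_volume():
    return g.simulate_null_volume((24, 24, 24), seed=7)


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (216 carriers, 136 non-carriers)."""
    return g.simulate_cohort(g.CohortSimSpec(seed=123))


@pytest.fixture(scope="session")
def prepared_cohort(cohort):
    table, _ = cohort
    return g.preprocess(table)
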