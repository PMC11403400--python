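import numpy as np
import pytest

from cpetphen import (
    SyntheticConfig,
    generate_cohort,
    preprocess_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small contaminated two-sex cohort with ground truth."""
    cfg = SyntheticConfig(n_per_sex=10, seed=11)
    recordings, participants, survivals, truth = generate_cohort(cfg)
    return cfg, recordings, participants, survivals, truth


@pytest.fixture(scope="session")
def small_cleaned(small_cohort):
    _, recordings, participants, survivals, truth = small_cohort
    cleaned, rejected = preprocess_cohort(recordings)
    assert not rejected
    return cleaned, participants, survivals, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
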