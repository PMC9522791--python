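import numpy as np
import pytest

from voxenc import CohortConfig, make_toy_lm, simulate_cohort
from voxenc.pipeline import score_cohort


@pytest.fixture(scope="session")
def toy_lm():
    return make_toy_lm(seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects x 2 stories, moderate noise: shared by integration tests."""
    cfg = CohortConfig(n_subjects=3, n_stories=2, n_words=300)
    return simulate_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    """Per-voxel brain scores for the shared cohort at the readout layer."""
    return score_cohort(small_cohort, layer=small_cohort.config.readout_layer)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
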