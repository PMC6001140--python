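import numpy as np
import pytest

from declina import CohortConfig, generate_cohort
from declina.scoring import score_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(n_participants=400, seed=42))


@pytest.fixture(scope="session")
def scored_cohort(small_cohort):
    return score_cohort(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
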