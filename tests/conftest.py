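import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hmiol.ensemble import train_ensemble
from hmiol.features import split_cohort
from hmiol.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def medium_cohort():
    """Moderate synthetic cohort with the default noisy Haigis ground truth."""
    return generate_cohort(CohortSpec(n=420, seed=101))


@pytest.fixture(scope="session")
def medium_split(medium_cohort):
    return split_cohort(medium_cohort, 0.8, seed=11)


@pytest.fixture(scope="session")
def trained_ensemble(medium_split):
    """Four-sub-model ensemble trained once per session on the medium cohort."""
    train, _ = medium_split
    return train_ensemble(train, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
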