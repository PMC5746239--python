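import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from comedclust import five_cluster_template, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_cohort():
    """Small fixed-seed synthetic cohort (n=60) shared across tests."""
    config = five_cluster_template(60, seed=42)
    profiles, covariates, planted = generate_cohort(config)
    return profiles, covariates, planted


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_distance_matrix(rng, n, scale=10.0):
    """Random symmetric zero-diagonal matrix with distinct entries."""
    a = rng.random((n, n)) * scale
    sq = (a + a.T) / 2
    np.fill_diagonal(sq, 0.0)
    return sq
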