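import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import radialforage as rf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_domain():
    """Four-point toy metric space: x=(1,2), y=(-2,4), p=(0,5), q=(3,1)
    relabeled 1..4."""
    return rf.load_fixture("example1_toy")


@pytest.fixture(scope="session")
def toy_D(toy_domain):
    return rf.distance_matrix(toy_domain)


@pytest.fixture(scope="session")
def animal1():
    return rf.load_fixture("table1_animal1")


@pytest.fixture(scope="session")
def animal1_D(animal1):
    return rf.distance_matrix(animal1)


@pytest.fixture
def random_domain():
    """Factory for seeded random domains without distance ties."""

    def make(n=10, seed=0, dims=2):
        rng = np.random.default_rng(seed)
        return rf.FoodDomain(
            tuple(range(1, n + 1)), rng.normal(0, 5, size=(n, dims))
        )

    return make
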