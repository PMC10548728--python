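import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hkascan import DemographicModel, LocusParams, SampleConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario1():
    """Deep-divergence study conditions: two species split 200k generations
    ago from an ancestor of 10k diploids."""
    return DemographicModel(N0=10_000, N1=10_000, N2=20_000, Td=200_000,
                            mu_ref=2.5e-8)


@pytest.fixture(scope="session")
def scenario2():
    """Recent-divergence study conditions (split 40k generations ago)."""
    return DemographicModel(N0=10_000, N1=10_000, N2=20_000, Td=40_000,
                            mu_ref=2.5e-8)


@pytest.fixture(scope="session")
def sample20():
    return SampleConfig(20, 20)


@pytest.fixture(scope="session")
def locus10kb():
    return LocusParams(mu_l=2.5e-8, length=10_000)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
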