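import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_sequence(rng):
    """Small random complex dynamic series."""
    from lps_dmri import DynamicImageSequence

    values = rng.normal(size=(8, 8, 5)) + 1j * rng.normal(size=(8, 8, 5))
    return DynamicImageSequence(values=values)


@pytest.fixture(scope="session")
def small_phantom():
    """Deterministic 64x64x16 phantom shared across tests."""
    from lps_dmri import PhantomConfig, generate_phantom

    return generate_phantom(PhantomConfig(seed=0))
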