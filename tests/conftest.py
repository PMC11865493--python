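import numpy as np
import pytest

from mitorestore.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_sample():
    """One default-geometry phantom shared across read-only tests."""
    return generate_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def degraded_phantom(phantom_sample):
    from mitorestore.degradation import DegradationParams, degrade

    return degrade(phantom_sample.hr_image, DegradationParams(seed=7))
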