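import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_protocol():
    """Scaled-down burst protocol: 10 ms bursts, 10 per sonication.

    With the default window layout this gives 47 analysis windows per burst,
    preserving the head/tail cuts and the 200 µs window length.
    """
    from sonoperm.exposure import FusProtocol

    return FusProtocol(pulse_length=0.010, n_pulses=10)


@pytest.fixture(scope="session")
def default_phantom():
    from sonoperm.simulate import Phantom

    return Phantom.cortex_slab()


@pytest.fixture(scope="session")
def small_phantom():
    from sonoperm.simulate import Phantom

    return Phantom.cortex_slab(shape=(32, 32, 4), margin=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
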