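import numpy as np
import pytest
from hypothesis import settings

from flowparse import ObserverParams

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noisy_observer():
    """Default synthetic observer: gain 0.5, 5 deg noise, 2% lapses."""
    return ObserverParams(beta=0.5, bias=0.0, noise_sd=5.0, lapse=0.02)
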