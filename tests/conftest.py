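import numpy as np
import pytest

from fnsynapse.params import DeviceParams, preset


@pytest.fixture(scope="session")
def params() -> DeviceParams:
    """Default device: Wc0 = 8 V, gamma = 4000, 250 ms pulses."""
    return DeviceParams()


@pytest.fixture(scope="session")
def gamma_presets():
    return preset("gamma1"), preset("gamma2")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
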