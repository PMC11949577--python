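import numpy as np
import pytest

from ratefield import NeuronParams


@pytest.fixture(scope="session")
def params() -> NeuronParams:
    """Reference single-population parameter set (external drive at 7 Hz)."""
    return NeuronParams(nu_ext=7.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
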