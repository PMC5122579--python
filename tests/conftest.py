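import numpy as np
import pytest

from synquant import ModelParams, SpikeTrain

from _util import FIG1


@pytest.fixture(scope="session")
def fig1_params() -> ModelParams:
    """The illustrative parameter set used throughout the figures."""
    return ModelParams(**FIG1)


@pytest.fixture(scope="session")
def regular_30hz() -> SpikeTrain:
    return SpikeTrain(np.arange(5) / 30.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
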