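import numpy as np
import pytest

from circrbp import synthetic


@pytest.fixture(scope="session")
def separable_world():
    return synthetic.separable_preset(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
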