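import numpy as np
import pytest

from rrqpop import design, synthetic


@pytest.fixture(scope="session")
def oacd():
    return design.build_oacd(12)


@pytest.fixture(scope="session")
def truth():
    return synthetic.default_truth(seed=7)


@pytest.fixture(scope="session")
def noiseless_truth():
    return synthetic.default_truth(seed=7, noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
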