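import numpy as np
import pytest

from transposim import ModelVariant, build_network, default_parameters

VARIANTS = tuple(v.value for v in ModelVariant)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def networks():
    return {v: build_network(v) for v in VARIANTS}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
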