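import numpy as np
import pytest

from evosim import build_k80, make_root_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def jc():
    return build_k80(1.0)


@pytest.fixture
def k80_2():
    return build_k80(2.0)


@pytest.fixture
def jc_sequence(jc, rng):
    return make_root_sequence(50, jc, rng)
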