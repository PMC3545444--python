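import numpy as np
import pytest

from myofil.mechanics import ActinMechanics, MyofilamentParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params():
    return MyofilamentParams()


@pytest.fixture
def actin():
    return ActinMechanics()
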