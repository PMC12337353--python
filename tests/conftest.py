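import numpy as np
import pytest

from panlv import build_space


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def space4():
    """L=4 doubletons: the worked example with K=6."""
    return build_space(4, 2)


@pytest.fixture(scope="session")
def space6():
    return build_space(6, 2)
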