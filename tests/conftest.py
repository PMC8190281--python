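import numpy as np
import pytest

from ctrlnet import connectome as cn
from ctrlnet import synth


def random_connectome(n, seed, density=0.9):
    """Small dense-ish random connectome for solver tests."""
    return synth.make_connectome(
        n_nodes=n, n_modules=1, density=density, seed=seed
    )


def random_system(n, seed, density=0.9):
    return cn.stabilize(random_connectome(n, seed, density))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def system10():
    return random_system(10, seed=42)


@pytest.fixture
def connectome10():
    return random_connectome(10, seed=42)
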