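import numpy as np
import pytest

from allopath import Selection
from allopath import synthetic_data as sd


@pytest.fixture(scope="session")
def helix20():
    return sd.make_helix(20, seed=7)


@pytest.fixture(scope="session")
def helix40():
    return sd.make_helix(40, seed=11)


@pytest.fixture(scope="session")
def interface_complex():
    return sd.make_interface_complex(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def chain_a():
    return Selection.chain("A")


@pytest.fixture(scope="session")
def chain_i():
    return Selection.chain("I")


def random_rigid_transform(rng):
    """A uniform random proper rotation + translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.uniform(-20, 20, size=3)
    return rot, trans
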