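import numpy as np
import pytest

from tomocoat.core import DensityMap, WedgeSpec
from tomocoat.synthetic_scene import build_leaf_phantom, default_leaf_spec


@pytest.fixture(scope="session")
def leaf_spec():
    return default_leaf_spec()


@pytest.fixture(scope="session")
def leaf(leaf_spec):
    return build_leaf_phantom(leaf_spec)


@pytest.fixture(scope="session")
def gap_leaf(leaf_spec):
    return build_leaf_phantom(leaf_spec, with_gap=True)


@pytest.fixture(scope="session")
def wedge60():
    return WedgeSpec(-60.0, 60.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
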