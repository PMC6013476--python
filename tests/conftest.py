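import numpy as np
import pytest

from snplast.geometry import make_maze
from snplast.protocols import ContinuousSim


@pytest.fixture(scope="session")
def open_maze():
    return make_maze("open")


@pytest.fixture(scope="session")
def obstacle_maze():
    return make_maze("open_obstacles")


@pytest.fixture(scope="session")
def tmaze():
    return make_maze("tmaze")


@pytest.fixture(scope="session")
def open_sim():
    return ContinuousSim("open")


@pytest.fixture(scope="session")
def tmaze_sim():
    return ContinuousSim("tmaze")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
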