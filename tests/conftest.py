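import numpy as np
import pytest
from hypothesis import settings

from meanfield_sca.graphs import make_torus_grid

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# the printed 3x3 worked example: states and neighbor counts over two
# deterministic majority-rule updates (1-based node order, row-major)
T0 = np.array([1, 1, 0, 1, 0, 0, 1, 1, 0])
R0 = np.array([3, 2, 2, 2, 3, 1, 3, 2, 2])
T1 = np.array([1, 0, 0, 0, 1, 0, 1, 0, 0])
R1 = np.array([1, 2, 1, 3, 0, 1, 1, 2, 1])
T2 = np.array([0, 0, 0, 1, 0, 0, 0, 0, 0])


@pytest.fixture(scope="session")
def torus3():
    return make_torus_grid(3)


@pytest.fixture(scope="session")
def torus10():
    return make_torus_grid(10)
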