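import numpy as np
import pytest

from mcrs import Params, make_fixture_lattice


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Small lattice, defaults otherwise."""
    return Params(n_grid=10, seed=7)


@pytest.fixture
def trio_lattice():
    """Three complementary specialists packed into one von Neumann mask.

    Centre (5,5) holds an activity-1 specialist; its north and west
    neighbours cover activities 2 and 3, so the activity sums at the centre
    are all positive.
    """
    rows = [
        (5, 5, [10.0, 0.0, 0.0], 2.0, 0),
        (4, 5, [0.0, 9.0, 0.0], 2.0, 1),
        (5, 4, [0.0, 0.0, 8.0], 2.0, 2),
    ]
    return make_fixture_lattice(rows, side=10, A=3)


@pytest.fixture
def random_lattice(rng):
    from mcrs import init_lattice

    return init_lattice(Params(n_grid=20, seed=3), rng)
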