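import numpy as np
import pytest

from tripledfc import synth
from tripledfc.core import BoldImage


@pytest.fixture(scope="session")
def tiny_design():
    """Miniature 2/2/2 cohort on a 12^3 grid — the smoke-test scale."""
    return synth.compact_design(grid_shape=(12, 12, 12),
                                group_sizes={"HC": 2, "SCD": 2, "aMCI": 2},
                                rng_seed=7)


@pytest.fixture(scope="session")
def small_design():
    """Slightly larger 4/4/4 cohort used where group statistics matter."""
    return synth.compact_design(grid_shape=(14, 14, 14),
                                group_sizes={"HC": 4, "SCD": 4, "aMCI": 4},
                                rng_seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_bold(rng, shape=(6, 6, 6), n_volumes=60, tr=2.0):
    affine = np.eye(4) * 3.0
    affine[3, 3] = 1.0
    return BoldImage(rng.standard_normal(shape + (n_volumes,)), affine, tr)
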