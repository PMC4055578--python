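import numpy as np
import pytest

from glossim import VegetationGrid, make_block


@pytest.fixture
def homogeneous_small():
    """31x31 all-good grid, cheap enough for iterated stepping."""
    return make_block(31, shape=(31, 31))


@pytest.fixture
def single_cell_habitat():
    """One good cell in a sea of no-go; degenerate habitat."""
    entry = np.zeros((9, 9))
    entry[4, 4] = 1.0
    return VegetationGrid(entry, layout_kind="block")


@pytest.fixture
def rng():
    return np.random.default_rng(20140612)
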