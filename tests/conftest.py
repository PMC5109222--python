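import numpy as np
import pytest
from hypothesis import settings

from semgimg import ElectrodeGrid, IntensityMap

# property tests run tiny examples; disable the wall-clock deadline so a
# loaded CI machine cannot flake them
settings.register_profile("ci", deadline=None)
settings.load_profile("ci")


@pytest.fixture
def grid8x16():
    return ElectrodeGrid(8, 16)


@pytest.fixture
def grid_small():
    return ElectrodeGrid(4, 4)


@pytest.fixture
def imap():
    return IntensityMap()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
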