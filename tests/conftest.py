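import numpy as np
import pytest

from peltrans.geometry import build_wall
from peltrans.model import ModelParams

#: 28 lattice rows: 28 * sqrt(3)/2 exactly commensurate
SMALL_BOX = (24.0, 24.24871130596428, 60.0)


@pytest.fixture(scope="session")
def small_geom():
    """Reduced-size membrane/pore geometry for fast interacting-system tests."""
    return build_wall(SMALL_BOX, pore_radius=2.25, pore_length=4.5, layers=4)


@pytest.fixture(scope="session")
def default_geom():
    return build_wall()


@pytest.fixture()
def params():
    return ModelParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
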