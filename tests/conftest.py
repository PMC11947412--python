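import numpy as np
import pytest

from kneetwin.contact import ContactParams
from kneetwin.ligament import set_reference_pose
from kneetwin.synthetic import (default_apparatus, neutral_reference_pose,
                                toy_surfaces)


@pytest.fixture(scope="session")
def surface():
    return toy_surfaces()


@pytest.fixture(scope="session")
def plane_surface():
    return toy_surfaces(dish_radius_mm=None)


@pytest.fixture(scope="session")
def params():
    return ContactParams()


@pytest.fixture(scope="session")
def apparatus(surface):
    """Default 12-strand apparatus referenced at the touching neutral pose."""
    app = default_apparatus(seed=0)
    return set_reference_pose(app, neutral_reference_pose(surface))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
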