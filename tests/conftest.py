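import numpy as np
import pytest

import minpat.model_core as mc
from minpat.meshing import build_mesh


@pytest.fixture(scope="session")
def pset():
    return mc.load_parameter_file()


@pytest.fixture(scope="session")
def rect_geo():
    return mc.CellGeometry("rectangle", 8.0, 2.0, 1.1, mesh_resolution=0.25)


@pytest.fixture(scope="session")
def rect_mesh(rect_geo):
    return build_mesh(rect_geo)


@pytest.fixture(scope="session")
def circle_mesh():
    g = mc.CellGeometry("ellipse", 2.0, 2.0, 1.1, mesh_resolution=0.2)
    return build_mesh(g)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
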