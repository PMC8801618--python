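import numpy as np
import pytest

from luxtomo import mesh_core as mc
from luxtomo import optical_props as op


@pytest.fixture
def single_tet_mesh():
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    return mc.make_mesh(nodes, [[0, 1, 2, 3]], [0], tissue_names={0: "A"})


@pytest.fixture
def two_tet_mesh():
    """Two tets sharing the face (1, 2, 3)."""
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]],
                     dtype=float)
    return mc.make_mesh(nodes, [[0, 1, 2, 3], [1, 2, 3, 4]], [0, 1],
                        tissue_names={0: "A", 1: "B"})


@pytest.fixture(scope="session")
def mouse_table_610():
    return op.digimouse_610_630(610)


@pytest.fixture(scope="session")
def two_region_sphere():
    """Small sphere phantom with a diffusive shell and an SP3 core, with a
    luminescent source inside the core (shared across forward-model tests)."""
    from luxtomo import experiments as ex

    mesh, S, table = ex.two_tissue_sphere(1.6)
    return mesh, S, table
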