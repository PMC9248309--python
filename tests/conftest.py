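import numpy as np
import pytest

import blurkit as bk


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_grid():
    """9^3 1-mm grid centered on the world origin."""
    return bk.VoxelGrid.isotropic(9, 1.0)


@pytest.fixture(scope="session")
def sheet():
    """Default folded cortical sheet (white, pial)."""
    return bk.make_cortical_sheet(bk.CorticalSheetSpec(), seed=0)


@pytest.fixture(scope="session")
def small_sheet():
    """Small sheet for fast projection/cluster tests."""
    return bk.make_cortical_sheet(
        bk.CorticalSheetSpec(extent=20.0, mean_vertex_spacing=2.0), seed=0)


@pytest.fixture(scope="session")
def icosahedron():
    """Closed genus-0 mesh with V=12, E=30, F=20."""
    phi = (1 + np.sqrt(5)) / 2
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], float)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ])
    return bk.TriangleMesh(verts, faces)


@pytest.fixture(scope="session")
def impulse_volume(small_grid):
    d = np.zeros(small_grid.dims)
    d[4, 4, 4] = 1.0
    return bk.Volume(small_grid, d)
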