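import numpy as np
import pytest

import cortexdem as cd
from cortexdem.surface import CorticalSurface


@pytest.fixture(scope="session")
def ico2():
    return cd.build_icosphere(2, 100.0)


@pytest.fixture(scope="session")
def ico3():
    return cd.build_icosphere(3, 100.0)


@pytest.fixture(scope="session")
def ico4():
    return cd.build_icosphere(4, 100.0)


def make_planar_patch(n=10, spacing=1.0):
    """Regular triangulated planar grid (n x n vertices) with a fake sphere
    projection (the patch pushed onto a large sphere) for API completeness."""
    xx, yy = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    verts = np.column_stack([xx.ravel() * spacing, yy.ravel() * spacing, np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces += [[a, a + 1, a + n + 1], [a, a + n + 1, a + n]]
    sphere = verts - verts.mean(0) + [0.0, 0.0, 500.0]
    sphere /= np.linalg.norm(sphere, axis=1, keepdims=True)
    return CorticalSurface(verts, np.asarray(faces), sphere)


@pytest.fixture(scope="session")
def planar():
    return make_planar_patch()


@pytest.fixture(scope="session")
def ens3_100(ico3):
    """Shared 100-member spin ensemble on the icosphere-3 mesh."""
    return cd.make_spins(ico3, 100, seed=3)
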