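import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from vasoring import (CBParams, CellParams, CUParams, RingGeometry,
                      TissueParams)


@pytest.fixture
def cell_params():
    return CellParams()


@pytest.fixture
def cb_params():
    return CBParams()


@pytest.fixture
def cu_params():
    return CUParams()


@pytest.fixture
def tissue_params():
    return TissueParams()


@pytest.fixture
def geometry():
    return RingGeometry()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_strip_system(nx=1, stretch=None, tissue=None, lengths=None):
    """A strip FE system with x-fibres; optionally prescribe end displacement."""
    import vasoring as v

    mesh = v.build_strip_mesh(nx, 1, 1, lengths=lengths or (float(nx), 1.0, 1.0))
    fib = np.zeros((mesh.n_elements, 8, 3))
    fib[:, :, 0] = 1.0
    fes = v.FESystem(mesh.nodes, mesh.elements, tissue or TissueParams(), fib)
    bcs = {}
    for n in mesh.node_sets["fix_x"]:
        bcs[(int(n), 0)] = 0.0
    for n in mesh.node_sets["fix_y"]:
        bcs[(int(n), 1)] = 0.0
    for n in mesh.node_sets["fix_z"]:
        bcs[(int(n), 2)] = 0.0
    if stretch is not None:
        lx = mesh.nodes[:, 0].max()
        for n in mesh.node_sets["hook_contact"]:
            bcs[(int(n), 0)] = (stretch - 1.0) * lx
    fes.set_dirichlet(bcs)
    return mesh, fes
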