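import numpy as np
import pytest

import blendsim as bs


@pytest.fixture
def geom():
    """Unit domain with interfaces at the thirds, D = 1 (the 1D study setup)."""
    return bs.build_geometry(0.0, 1.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)


@pytest.fixture
def mesh_pc(geom):
    return bs.build_mesh(geom, 1.0 / 300.0, 1.0 / 30.0, "pde-compartment")


@pytest.fixture
def mesh_cb(geom):
    return bs.build_mesh(geom, 1.0 / 300.0, 1.0 / 30.0, "compartment-brownian")


@pytest.fixture
def geom3d():
    """The 3D bimolecular domain [0,10] x [0,1] x [0,1]."""
    return bs.build_geometry(0.0, 10.0, 10.0 / 3.0, 20.0 / 3.0, 1.0,
                             dimension=3)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
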