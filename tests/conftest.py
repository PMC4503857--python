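import numpy as np
import pytest

from molcanvas import fixtures as fx


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def benzene():
    return fx.benzene()


@pytest.fixture
def naphthalene():
    return fx.naphthalene()


@pytest.fixture
def water3d():
    return fx.water_xyz()


def assert_molecules_equal(a, b, coord_tol=1e-4):
    """Value equality: same atoms (label/coords/charge) and bonds."""
    assert len(a.atoms) == len(b.atoms)
    assert len(a.bonds) == len(b.bonds)
    for x, y in zip(a.atoms, b.atoms):
        assert x.label == y.label
        assert x.charge == y.charge
        assert abs(x.x - y.x) <= coord_tol
        assert abs(x.y - y.y) <= coord_tol
        assert abs(x.z - y.z) <= coord_tol
    assert {(b_.pair(), b_.order, b_.stereo) for b_ in a.bonds} \
        == {(b_.pair(), b_.order, b_.stereo) for b_ in b.bonds}
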