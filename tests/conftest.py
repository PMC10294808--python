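import numpy as np
import pytest

from ldhsim import mc, protocols
from ldhsim.structure import UnitCell, build_pyroaurite, build_supercell


@pytest.fixture(scope="session")
def hex_cell():
    return UnitCell.hexagonal(12.4, 23.41)


@pytest.fixture(scope="session")
def unit_framework(hex_cell):
    return build_pyroaurite(0.25, 4.5, hex_cell, seed=0)


@pytest.fixture(scope="session")
def supercell(unit_framework):
    return build_supercell(unit_framework, (3, 3, 2))


@pytest.fixture(scope="session")
def slab_protocol_result():
    """The scaled-down tetracycline-on-slab simulation (1e5 + 1e5 steps).

    Expensive (minutes); shared by every test that inspects the
    equilibrated surface configurations.
    """
    return protocols.slab_protocol(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_box(a=26.0):
    """An empty cubic periodic box big enough for the default cutoff."""
    from ldhsim.structure import Framework

    return Framework(UnitCell(a, a, a), np.zeros((0, 3)), [])
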