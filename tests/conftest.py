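import numpy as np
import pytest

from lattpart.forcefield import ForceFieldConfig, ToyForceField
from lattpart.model import CrystalStructure, Molecule
from lattpart.synthetic import make_chain_molecule


@pytest.fixture
def ff():
    return ToyForceField()


@pytest.fixture
def cfg():
    return ForceFieldConfig(cutoff=9.0)


@pytest.fixture
def butane():
    """4-atom united-atom chain with one rotatable torsion (anti minimum)."""
    return make_chain_molecule(n_atoms=4)


@pytest.fixture
def hexane():
    """6-atom chain with three rotatable torsions."""
    return make_chain_molecule(n_atoms=6)


def lj_site_crystal(a: float = 4.0, sigma: float = 3.4,
                    epsilon: float = 1.0) -> CrystalStructure:
    """Single Lennard-Jones site per cell on a simple cubic lattice."""
    mol = Molecule(
        elements=("Ar",), coords=np.zeros((1, 3)), charges=np.zeros(1),
        bonds=(), bond_params=(), sigma=np.array([sigma]),
        epsilon=np.array([epsilon]), compound_id="lj-site",
    )
    return CrystalStructure(np.eye(3) * a, [mol], "lj-sc", "lj-site")


@pytest.fixture
def lj_sc():
    return lj_site_crystal()
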