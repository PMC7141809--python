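import numpy as np
import pytest

from ionpore.core import Atom, Structure, sigma_scale
from ionpore.synthetic import make_toy_channel, paired_ion_maps


@pytest.fixture(scope="session")
def toy_channel():
    structure, truth = make_toy_channel(seed=0)
    return structure, truth


@pytest.fixture(scope="session")
def closed_channel():
    structure, truth = make_toy_channel(constriction_radius=0.5, seed=0)
    return structure, truth


@pytest.fixture(scope="session")
def paired_maps(toy_channel):
    """Default paired-map scenario: 4 ions, 12 waters, amplitude ratio 3."""
    structure, _ = toy_channel
    map_primary, map_partner, truth = paired_ion_maps(structure, seed=0)
    return sigma_scale(map_primary), sigma_scale(map_partner), truth, structure


def make_ring(radius, n=8, z=0.0, element="C", resname="LEU"):
    """Ring of atoms around the z axis; analytic pore radius = radius - vdW."""
    atoms = [
        Atom(
            element=element,
            atom_name=f"C{i + 1}",
            residue_name=resname,
            residue_number=30 + i,
            chain_id="A",
            position=np.array([radius * np.cos(2 * np.pi * i / n),
                               radius * np.sin(2 * np.pi * i / n), z]),
        )
        for i in range(n)
    ]
    return Structure(atoms=atoms, label=f"ring-{radius:g}")


@pytest.fixture
def three_atom_structure():
    """Minimal fixture with one protein, one ion and one water atom."""
    return Structure(atoms=[
        Atom(element="C", atom_name="CA", residue_name="ALA", residue_number=1,
             chain_id="A", position=np.array([0.0, 0.0, 0.0])),
        Atom(element="K", atom_name="K", residue_name="K", residue_number=101,
             chain_id="B", position=np.array([3.0, 0.0, 0.0])),
        Atom(element="O", atom_name="O", residue_name="HOH", residue_number=201,
             chain_id="C", position=np.array([0.0, 3.0, 0.0])),
    ], label="three-atoms")
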