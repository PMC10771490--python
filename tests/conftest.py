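import numpy as np
import pytest

from septkit.structure_io import Atom, Chain, Residue, Structure
from septkit.synthetic_data import make_ideal_helix, make_interface_dimer


@pytest.fixture(scope="session")
def helix30() -> Structure:
    return make_ideal_helix(30)


@pytest.fixture(scope="session")
def dimer_bundle():
    return make_interface_dimer(seed=7)


def single_atom_structure(element: str = "C", position=(0.0, 0.0, 0.0)) -> Structure:
    atom = Atom(name="CA", element=element, position=np.asarray(position, float))
    return Structure(identifier="single",
                     chains=[Chain("A", [Residue(1, "ALA", [atom])])])


def n_atom_structure(positions, elements=None) -> Structure:
    """One chain, one residue per atom; for small geometric SASA fixtures."""
    positions = np.asarray(positions, float)
    elements = elements or ["C"] * len(positions)
    residues = [
        Residue(i + 1, "ALA", [Atom(name="CA", element=el, position=pos)])
        for i, (pos, el) in enumerate(zip(positions, elements))
    ]
    return Structure(identifier="cluster", chains=[Chain("A", residues)])
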