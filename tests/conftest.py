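import numpy as np
import pytest

from kinnet import synthetic_data as sd
from kinnet.structio import Atom, ConformationalEnsemble, Residue, Structure


@pytest.fixture(scope="session")
def helix10():
    return sd.gen_toy_structure(10, "helix", seed=1)


@pytest.fixture(scope="session")
def complex_pair():
    return sd.gen_complex(sd.ComplexSpec(seed=1))


@pytest.fixture(scope="session")
def holo_static_ensemble(complex_pair):
    _, holo = complex_pair
    return ConformationalEnsemble(topology=holo, frames=np.stack([holo.coords()] * 3))


def make_point_structure(points, res_type="LIG", element="C", radius=1.7):
    """One single-atom ligand residue per coordinate (for pair-energy toys)."""
    residues = []
    for k, xyz in enumerate(points):
        atom = Atom(k + 1, f"X{k + 1}", element, k, np.asarray(xyz, float), True, radius)
        residues.append(Residue(chr(65 + k), 1, res_type, [atom], is_ligand=True))
    return Structure(residues)


@pytest.fixture
def point_structure_factory():
    return make_point_structure
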