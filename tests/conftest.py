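import numpy as np
import pytest
import biotite.structure as struc

from loopdyn.ensembles import Ensemble, StructureModel
from loopdyn.geometry import build_backbone


def make_model(atoms):
    arr = struc.array(atoms)
    arr.set_annotation("b_factor", np.zeros(arr.array_length()))
    arr.set_annotation("occupancy", np.ones(arr.array_length()))
    return StructureModel(arr)


def backbone_model(n_residues, phi, psi, chain_id="A", res_names=None):
    """Single-conformer model with an ideal (phi, psi) backbone."""
    bb = build_backbone(n_residues, phi, psi)
    atoms = []
    for i in range(n_residues):
        name = (res_names or ["ALA"] * n_residues)[i]
        for atom in ("N", "CA", "C", "O"):
            atoms.append(struc.Atom(bb[atom][i], chain_id=chain_id,
                                    res_id=i + 1, res_name=name,
                                    atom_name=atom, element=atom[0]))
    return make_model(atoms)


@pytest.fixture
def helix_ensemble():
    model = backbone_model(6, -57.0, -47.0)
    return Ensemble(model, model.atoms.coord[None, :, :])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
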