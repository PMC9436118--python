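import numpy as np
import pytest

from speach_af.fixtures import HingeToySpec, hinge_model, make_hinge_ensemble


@pytest.fixture(scope="session")
def toy_spec():
    return HingeToySpec()


@pytest.fixture(scope="session")
def closed_toy(toy_spec):
    """Near-closed noise-free hinge toy: the arms make heavy-atom contacts."""
    return hinge_model(toy_spec, 2.0, model_id="closed")


@pytest.fixture(scope="session")
def open_toy(toy_spec):
    return hinge_model(toy_spec, 55.0, model_id="open")


@pytest.fixture(scope="session")
def toy_ensemble(toy_spec):
    return make_hinge_ensemble(toy_spec, 20, seed=7)


def random_rigid_motion(rng: np.random.Generator):
    """A random proper rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-50, 50, 3)
    return R, t


def apply_rigid(model, R, t):
    """Rigidly transform a StructureModel (fresh copy)."""
    from speach_af.structures import Residue, StructureModel

    residues = []
    for res in model.residues:
        atoms = [
            (name, *(R @ np.array([x, y, z]) + t)) for name, x, y, z in res.atoms
        ]
        residues.append(Residue(res.number, res.name, atoms, res.plddt))
    return StructureModel(model_id=model.model_id + "_moved", residues=residues)
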