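import pytest

from thermofluct.core import Atom, Structure
from thermofluct.synthetic import FluctuationSpec, make_reference_structure, make_trajectory


@pytest.fixture(scope="session")
def reference_50():
    """A 50-residue coarse reference structure."""
    return make_reference_structure(50, seed=11)


@pytest.fixture(scope="session")
def noisy_trajectory(reference_50):
    """300 frames, sigma 0.4 A per axis, rigid-body noise on."""
    spec = FluctuationSpec.uniform(
        50, 0.4, rigid_body_noise=(8.0, 1.5), seed=12
    )
    return make_trajectory(reference_50, spec, [], n_frames=300)


def _tiny_structure(positions, residue_names=None, atom_names=None):
    residue_names = residue_names or ["ALA"] * len(positions)
    atom_names = atom_names or ["CA"] * len(positions)
    atoms = [
        Atom("A", i + 1, residue_names[i], atom_names[i], atom_names[i][0], p)
        for i, p in enumerate(positions)
    ]
    return Structure(atoms, name="tiny")


@pytest.fixture
def tiny_structure_factory():
    return _tiny_structure
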