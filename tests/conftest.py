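import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kinrank.structures import Atom, StructureRecord
from kinrank.synthetic import make_toy_kinase, toy_residue_map


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a translation up to 20 Å."""
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t


def make_protein(n_residues: int = 12, seed: int = 0, chain: str = "A",
                 structure_id: str = "prot") -> StructureRecord:
    """Small all-Cα protein with reproducible random coordinates."""
    rng = np.random.default_rng(seed)
    atoms = [
        Atom(chain, i + 1, "ALA", "CA", "C", rng.uniform(-15, 15, size=3))
        for i in range(n_residues)
    ]
    return StructureRecord(structure_id, atoms)


def make_holo(n_residues: int = 12, n_ligand: int = 6, seed: int = 0,
              structure_id: str = "holo") -> StructureRecord:
    """Protein plus a rigid ligand of named heavy atoms."""
    rng = np.random.default_rng(seed)
    prot = make_protein(n_residues, seed=seed, structure_id=structure_id)
    lig = [
        Atom("L", 900, "LIG", f"C{i+1}", "C", rng.uniform(-5, 5, size=3))
        for i in range(n_ligand)
    ]
    return StructureRecord(structure_id, prot.atoms, lig)


@pytest.fixture
def toy_kinase():
    return make_toy_kinase(d1=9.0, d2=13.0, aloop_distance=10.0)


@pytest.fixture
def toy_map():
    return toy_residue_map()
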