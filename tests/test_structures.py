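"""Structure I/O, Kabsch superposition, ligand RMSD and ensemble filtering."""

import numpy as np
import pytest

from kinrank.structures import (
    Atom,
    StructureRecord,
    StructureError,
    read_structure,
    write_structure,
    superpose,
    kabsch,
    ligand_rmsd,
    filter_ensemble,
)

from conftest import make_holo, make_protein, random_rigid_motion


THREE_ATOM_PDB = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00 90.00           C
ATOM      2  CA  ALA A   2       4.000   5.000   6.000  1.00 85.00           C
ATOM      3  CB  ALA A   2       7.500  -1.250   0.125  1.00 80.00           C
END
"""


class TestReadWrite:
    def test_hand_written_pdb_coordinates_echoed(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(THREE_ATOM_PDB)
        s = read_structure(p)
        assert len(s.atoms) == 3 and not s.ligand_atoms
        np.testing.assert_allclose(s.atoms[0].position, [1, 2, 3], atol=1e-3)
        np.testing.assert_allclose(s.atoms[2].position, [7.5, -1.25, 0.125], atol=1e-3)
        assert s.atoms[0].b_factor == pytest.approx(90.0)
        assert (s.atoms[1].chain_id, s.atoms[1].residue_number, s.atoms[1].atom_name) == (
            "A", 2, "CA",
        )

    def test_ligand_resname_selection(self, tmp_path):
        text = THREE_ATOM_PDB.replace("END\n", "") + (
            "HETATM    4  C1  STI L 900      10.000  11.000  12.000  1.00  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "lig.pdb"
        p.write_text(text)
        s = read_structure(p, ligand_resnames={"STI"})
        assert len(s.atoms) == 3
        assert [a.atom_name for a in s.ligand_atoms] == ["C1"]

    def test_round_trip_preserves_atom_table(self, tmp_path):
        orig = make_holo(n_residues=8, seed=3)
        path = tmp_path / "out.pdb"
        write_structure(orig, path)
        back = read_structure(path, ligand_resnames={"LIG"})
        assert len(back.atoms) == len(orig.atoms)
        assert len(back.ligand_atoms) == len(orig.ligand_atoms)
        for a, b in zip(orig.atoms, back.atoms):
            assert (a.chain_id, a.residue_number, a.atom_name) == (
                b.chain_id, b.residue_number, b.atom_name,
            )
            np.testing.assert_allclose(a.position, b.position, atol=1e-3)

    def test_unparseable_file_raises(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_bytes(b"\x00\x01 not a pdb")
        with pytest.raises(StructureError):
            read_structure(p)

    def test_empty_structure_rejected(self):
        with pytest.raises(StructureError):
            StructureRecord("empty", [])


class TestSuperpose:
    def test_identity(self):
        s = make_protein(seed=1)
        sup = superpose(s, s)
        assert sup.rmsd < 1e-9
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)
        assert sup.n_atoms_used == len(s.atoms)

    def test_rigid_motion_exactly_removed(self):
        s = make_protein(seed=2)
        theta = np.deg2rad(37)
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        moved = s.transformed(R, np.array([1.0, 2.0, 3.0]))
        assert superpose(moved, s).rmsd < 1e-6

    def test_matches_brute_force_rotation_search(self):
        """Kabsch RMSD equals a grid+refine minimization over rotations."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(7)
        a = rng.normal(size=(10, 3))
        b = a + rng.normal(scale=0.3, size=(10, 3))
        sup = kabsch(a, b)

        ac, bc = a - a.mean(0), b - b.mean(0)

        def cost(rotvec):
            R = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(np.mean(np.sum((ac @ R.T - bc) ** 2, axis=1)))

        best = np.inf
        for x0 in rng.uniform(-np.pi, np.pi, size=(40, 3)):
            res = minimize(cost, x0, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12})
            best = min(best, res.fun)
        assert sup.rmsd == pytest.approx(best, abs=1e-4)

    def test_rmsd_invariant_to_rigid_motion_of_mobile(self):
        ref = make_protein(seed=4)
        mobile = make_protein(seed=5)
        base = superpose(mobile, ref).rmsd
        rng = np.random.default_rng(11)
        for _ in range(20):
            R, t = random_rigid_motion(rng)
            assert abs(superpose(mobile.transformed(R, t), ref).rmsd - base) < 1e-6

    def test_too_few_atoms(self):
        a = make_protein(n_residues=2, seed=1)
        b = make_protein(n_residues=2, seed=1)
        with pytest.raises(StructureError, match="matched atoms"):
            superpose(a, b)

    def test_collinear_selection_warns_but_returns(self):
        atoms_a = [Atom("A", i, "ALA", "CA", "C", np.array([float(i), 0, 0]))
                   for i in range(5)]
        atoms_b = [Atom("A", i, "ALA", "CA", "C", np.array([float(i), 0.0, 0.0]))
                   for i in range(5)]
        with pytest.warns(UserWarning, match="collinear"):
            sup = superpose(StructureRecord("a", atoms_a), StructureRecord("b", atoms_b))
        assert sup.rmsd < 1e-9


class TestLigandRmsd:
    def test_identity_pose(self):
        holo = make_holo(seed=6)
        assert ligand_rmsd(holo, holo) < 1e-9

    def test_pure_ligand_translation_is_closed_form(self):
        holo = make_holo(seed=8)
        shifted = StructureRecord(
            "pose",
            holo.atoms,
            [Atom(a.chain_id, a.residue_number, a.residue_name, a.atom_name,
                  a.element, a.position + np.array([0.0, 3.0, 0.0]))
             for a in holo.ligand_atoms],
        )
        assert ligand_rmsd(shifted, holo) == pytest.approx(3.0, abs=1e-9)

    def test_arbitrary_pose_matches_direct_formula(self):
        """RMSD equals sqrt(mean ||Δr||²) computed independently after the fit."""
        rng = np.random.default_rng(9)
        holo = make_holo(seed=9)
        pose = StructureRecord(
            "pose",
            holo.atoms,
            [Atom(a.chain_id, a.residue_number, a.residue_name, a.atom_name,
                  a.element, a.position + rng.normal(scale=1.0, size=3))
             for a in holo.ligand_atoms],
        )
        got = ligand_rmsd(pose, holo)
        # independent direct formula: same protein => identity superposition
        deltas = [
            p.position - r.position
            for p, r in zip(pose.ligand_atoms, holo.ligand_atoms)
        ]
        expected = np.sqrt(np.mean([d @ d for d in deltas]))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_unmatched_ligand_atoms_listed(self):
        holo = make_holo(seed=10)
        partial = StructureRecord("pose", holo.atoms, holo.ligand_atoms[:-1])
        with pytest.raises(StructureError, match=holo.ligand_atoms[-1].atom_name):
            ligand_rmsd(partial, holo)

    def test_empty_ligand_rejected(self):
        prot = make_protein(seed=11)
        holo = make_holo(seed=11)
        with pytest.raises(StructureError, match="no ligand"):
            ligand_rmsd(prot, holo)


class TestFilterEnsemble:
    @staticmethod
    def _decoy_at_rmsd(reference, target_rmsd, seed):
        """Displace half the atoms so the optimally-fit Cα RMSD hits the target."""
        rng = np.random.default_rng(seed)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        n = len(reference.atoms)
        atoms = []
        for i, a in enumerate(reference.atoms):
            # antisymmetric displacement: centroid unchanged, no net rotation gain
            sign = 1.0 if i % 2 == 0 else -1.0
            atoms.append(
                Atom(a.chain_id, a.residue_number, a.residue_name, a.atom_name,
                     a.element, a.position + sign * target_rmsd * direction)
            )
        s = StructureRecord(f"decoy{seed}", atoms)
        return s

    def test_constructed_split(self):
        ref = make_protein(n_residues=20, seed=12)
        near = [self._decoy_at_rmsd(ref, 1.0, s) for s in range(7)]
        far = [self._decoy_at_rmsd(ref, 20.0, s) for s in range(7, 10)]
        kept, discarded = filter_ensemble(near + far, ref, rmsd_cutoff=7.0)
        assert [d.id for d in kept] == [d.id for d in near]
        assert len(discarded) == 3

    def test_infinite_cutoff_keeps_everything(self):
        ref = make_protein(seed=13)
        decoys = [self._decoy_at_rmsd(ref, 30.0, s) for s in range(4)]
        kept, discarded = filter_ensemble(decoys, ref, rmsd_cutoff=np.inf)
        assert kept == decoys and not discarded

    def test_boundary_is_inclusive(self):
        """Only strictly-greater RMSDs are discarded."""
        ref = make_protein(n_residues=20, seed=14)
        decoy = self._decoy_at_rmsd(ref, 5.0, 99)
        from kinrank.structures import superpose as sp
        actual = sp(decoy, ref).rmsd
        kept, discarded = filter_ensemble([decoy], ref, rmsd_cutoff=actual)
        assert kept and not discarded

    def test_idempotent(self):
        ref = make_protein(n_residues=20, seed=15)
        decoys = [self._decoy_at_rmsd(ref, r, s) for s, r in enumerate([1, 3, 20, 25])]
        kept1, _ = filter_ensemble(decoys, ref)
        kept2, _ = filter_ensemble(kept1, ref)
        assert kept1 == kept2
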