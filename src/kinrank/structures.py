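"""Protein structure I/O, superposition and RMSD utilities.

Structures are held in a light-weight :class:`StructureRecord` backed by plain
numpy arrays. PDB parsing and writing go through biotite; rigid-body fitting
uses the Kabsch algorithm (proper rotation enforced).

All RMSDs in this package are heavy-atom; hydrogens are dropped on read.
Residue numbering is the author numbering of the input file — no renumbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile


class StructureError(ValueError):
    """Raised for unreadable files, empty selections or unmatched atoms."""


@dataclass(eq=False)
class Atom:
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # (3,) in Å
    b_factor: float = 0.0  # carries pLDDT for AF2 models
    insertion_code: str = ""

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.residue_number, self.insertion_code, self.atom_name)


@dataclass(eq=False)
class StructureRecord:
    """One protein model (plus optional ligand atoms)."""

    id: str
    atoms: list[Atom] = field(default_factory=list)
    ligand_atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.atoms) + len(self.ligand_atoms) == 0:
            raise StructureError(f"structure {self.id!r} has no atoms")
        coords = self.coords()
        if coords.size and not np.all(np.isfinite(coords)):
            raise StructureError(f"structure {self.id!r} has non-finite coordinates")
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise StructureError(f"structure {self.id!r} has duplicate protein atoms")

    def coords(self, ligand: bool = False) -> np.ndarray:
        atoms = self.ligand_atoms if ligand else self.atoms
        if not atoms:
            return np.zeros((0, 3))
        return np.stack([a.position for a in atoms])

    def atom_index(self) -> dict[tuple, int]:
        return {a.key: i for i, a in enumerate(self.atoms)}

    def get_atom(self, chain_id: str, residue_number: int, atom_name: str) -> Atom:
        for a in self.atoms:
            if (
                a.chain_id == chain_id
                and a.residue_number == residue_number
                and a.atom_name == atom_name
            ):
                return a
        raise StructureError(
            f"atom ({chain_id}, {residue_number}, {atom_name}) not found in {self.id!r}"
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureRecord":
        """Return a copy with ``x -> R x + t`` applied to every atom."""

        def _apply(atoms: list[Atom]) -> list[Atom]:
            return [
                Atom(
                    a.chain_id,
                    a.residue_number,
                    a.residue_name,
                    a.atom_name,
                    a.element,
                    rotation @ a.position + translation,
                    a.b_factor,
                    a.insertion_code,
                )
                for a in atoms
            ]

        return StructureRecord(self.id, _apply(self.atoms), _apply(self.ligand_atoms))


@dataclass(eq=False)
class Superposition:
    """Least-squares rigid-body fit of a mobile onto a reference structure."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float  # Å, over the matched atoms after the fit
    n_atoms_used: int

    def __post_init__(self) -> None:
        assert abs(np.linalg.det(self.rotation) - 1.0) < 1e-8
        assert self.rmsd >= 0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


_HYDROGEN = {"H", "D"}


def _atoms_from_array(arr: "struc.AtomArray") -> list[Atom]:
    out = []
    for i in range(arr.array_length()):
        out.append(
            Atom(
                chain_id=str(arr.chain_id[i]),
                residue_number=int(arr.res_id[i]),
                residue_name=str(arr.res_name[i]),
                atom_name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                position=np.asarray(arr.coord[i], dtype=float).copy(),
                b_factor=float(arr.b_factor[i]) if "b_factor" in arr.get_annotation_categories() else 0.0,
                insertion_code=str(arr.ins_code[i]) if "ins_code" in arr.get_annotation_categories() else "",
            )
        )
    return out


def read_structure(
    path: str | Path,
    protein_chains: Iterable[str] | None = None,
    ligand_resnames: Iterable[str] | None = None,
    structure_id: str | None = None,
) -> StructureRecord:
    """Read the first model of a PDB file into a :class:`StructureRecord`.

    Atoms whose residue name is in ``ligand_resnames`` go to ``ligand_atoms``;
    water is dropped; hydrogens are dropped; for altloc'd atoms the
    highest-occupancy conformer is kept. Insertion codes are preserved.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, extra_fields=["b_factor", "occupancy"])
    except Exception as exc:  # biotite raises various parse errors
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc

    arr = arr[~np.isin(arr.element, list(_HYDROGEN))]
    arr = arr[arr.res_name != "HOH"]

    ligand_set = set(ligand_resnames or ())
    is_ligand = np.isin(arr.res_name, list(ligand_set)) if ligand_set else np.zeros(arr.array_length(), bool)

    protein = arr[~is_ligand]
    if protein_chains is not None:
        protein = protein[np.isin(protein.chain_id, list(protein_chains))]
    ligand = arr[is_ligand]

    atoms = _atoms_from_array(protein)
    lig_atoms = _atoms_from_array(ligand)
    if not atoms and not lig_atoms:
        raise StructureError(f"empty selection reading {path}")
    return StructureRecord(structure_id or path.stem, atoms, lig_atoms)


def write_structure(structure: StructureRecord, path: str | Path) -> None:
    """Write a StructureRecord as a standard 80-column PDB file."""
    all_atoms = list(structure.atoms) + list(structure.ligand_atoms)
    n = len(all_atoms)
    arr = struc.AtomArray(n)
    arr.coord = np.stack([a.position for a in all_atoms])
    arr.chain_id = np.array([a.chain_id for a in all_atoms])
    arr.res_id = np.array([a.residue_number for a in all_atoms])
    arr.res_name = np.array([a.residue_name for a in all_atoms])
    arr.atom_name = np.array([a.atom_name for a in all_atoms])
    arr.element = np.array([a.element for a in all_atoms])
    arr.set_annotation("b_factor", np.array([a.b_factor for a in all_atoms]))
    arr.set_annotation("ins_code", np.array([a.insertion_code for a in all_atoms]))
    arr.set_annotation(
        "hetero",
        np.array([False] * len(structure.atoms) + [True] * len(structure.ligand_atoms)),
    )
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def _match_atoms(
    mobile: StructureRecord,
    reference: StructureRecord,
    selection: str | Sequence[str] = "CA",
) -> tuple[np.ndarray, np.ndarray]:
    """Pair atoms by (chain, residue_number, ins_code, atom_name).

    ``selection`` is an atom-name or list of atom names ("all" keeps every
    shared protein atom).
    """
    if selection == "all":
        wanted = None
    elif isinstance(selection, str):
        wanted = {selection}
    else:
        wanted = set(selection)

    ref_index = {
        a.key: a.position for a in reference.atoms if wanted is None or a.atom_name in wanted
    }
    mob, ref = [], []
    for a in mobile.atoms:
        if wanted is not None and a.atom_name not in wanted:
            continue
        pos = ref_index.get(a.key)
        if pos is not None:
            mob.append(a.position)
            ref.append(pos)
    return np.asarray(mob, float), np.asarray(ref, float)


def kabsch(mobile_xyz: np.ndarray, reference_xyz: np.ndarray) -> Superposition:
    """Least-squares rigid fit of ``mobile_xyz`` onto ``reference_xyz``."""
    mobile_xyz = np.asarray(mobile_xyz, float)
    reference_xyz = np.asarray(reference_xyz, float)
    if mobile_xyz.shape != reference_xyz.shape or mobile_xyz.ndim != 2:
        raise StructureError("coordinate sets must have identical (n, 3) shapes")
    n = mobile_xyz.shape[0]
    if n < 3:
        raise StructureError(f"superposition needs >= 3 matched atoms, got {n}")

    mob_c = mobile_xyz.mean(axis=0)
    ref_c = reference_xyz.mean(axis=0)
    a = mobile_xyz - mob_c
    b = reference_xyz - ref_c

    # collinearity check: second singular value ~ 0
    s = np.linalg.svd(a, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        warnings.warn("degenerate (collinear) selection for superposition", stacklevel=2)

    # align_vectors solves Wahba's problem = Kabsch with proper rotation
    rot, _ = Rotation.align_vectors(b, a)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    fitted = a @ R.T + ref_c
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference_xyz) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms_used=n)


def superpose(
    mobile: StructureRecord,
    reference: StructureRecord,
    selection: str | Sequence[str] = "CA",
) -> Superposition:
    """Kabsch fit of ``mobile`` onto ``reference`` over matched atoms.

    Atoms are matched by (chain, residue number, insertion code, atom name).
    """
    mob, ref = _match_atoms(mobile, reference, selection)
    if len(mob) < 3:
        raise StructureError(
            f"superposition of {mobile.id!r} on {reference.id!r}: "
            f"only {len(mob)} matched atoms (need >= 3)"
        )
    return kabsch(mob, ref)


def ligand_rmsd(
    pose: StructureRecord,
    reference_holo: StructureRecord,
    align_selection: str | Sequence[str] = "CA",
    ligand_match: str = "atom_name",
) -> float:
    """Heavy-atom ligand RMSD after superposing the pose protein on the reference.

    The ligand is *not* re-fitted: the protein superposition is applied to the
    pose ligand and the deviation from the reference ligand is measured over
    atoms paired by name. Not symmetry-corrected.
    """
    if not reference_holo.ligand_atoms:
        raise StructureError("reference structure has no ligand atoms")
    if not pose.ligand_atoms:
        raise StructureError("pose has no ligand atoms")
    if ligand_match != "atom_name":
        raise StructureError(f"unknown ligand_match rule {ligand_match!r}")

    sup = superpose(pose, reference_holo, align_selection)

    pose_by_name = {a.atom_name: a.position for a in pose.ligand_atoms}
    missing = [a.atom_name for a in reference_holo.ligand_atoms if a.atom_name not in pose_by_name]
    if missing:
        raise StructureError(f"pose ligand is missing atoms: {missing}")

    ref_xyz = np.stack([a.position for a in reference_holo.ligand_atoms])
    pose_xyz = np.stack([pose_by_name[a.atom_name] for a in reference_holo.ligand_atoms])
    pose_fit = sup.apply(pose_xyz)
    return float(np.sqrt(np.mean(np.sum((pose_fit - ref_xyz) ** 2, axis=1))))


def filter_ensemble(
    decoys: Sequence[StructureRecord],
    reference: StructureRecord,
    rmsd_cutoff: float = 7.0,
    selection: str | Sequence[str] = "CA",
) -> tuple[list[StructureRecord], list[StructureRecord]]:
    """Discard decoys whose superposed RMSD to the reference exceeds the cutoff.

    The default 7 Å Cα cutoff removes unphysical models from an AF2 decoy
    ensemble; a decoy at exactly the cutoff is kept (only strictly greater
    values are discarded).
    """
    kept, discarded = [], []
    for decoy in decoys:
        sup = superpose(decoy, reference, selection)
        (kept if sup.rmsd <= rmsd_cutoff else discarded).append(decoy)
    return kept, discarded
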