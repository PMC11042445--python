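"""Kinase order parameters and conformational classification.

Implements the geometric descriptors used throughout the pipeline:

* **Dunbrack coordinates** D1/D2 — distances from the DFG-Phe ζ-carbon (CZ)
  to the Cα of an αC-helix anchor residue (D1) and of the β3 lysine (D2).
  They separate DFG-in, DFG-out and intermediate (inter) conformations.
* **A-loop distance** — a single inter-residue distance (e.g. Cβ–Cβ of
  N98/R162 in Abl1, cutoff 15 Å; the E110/R191 salt-bridge pair in DDR1,
  cutoff 10 Å) classifying the activation loop as folded or extended.
* **Collective variables (CVs)** — an ordered list of pairwise atom
  distances (14 in the default kinase configuration) describing the
  ATP-pocket/A-loop region; these feed the latent-space model.
* **αC-helix integrity** — fraction of trajectory frames in which the αC
  helix is broken, used to exclude corrupted umbrella-sampling windows.

Residue maps and CV specs are user-supplied configuration (YAML/JSON); the
pair lists differ per kinase and are never hard-coded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .structures import StructureRecord, StructureError

AtomRef = tuple[str, int, str]  # (chain, residue_number, atom_name)


@dataclass
class ResidueMap:
    """Anchor residues/atoms defining the order parameters for one kinase."""

    kinase_name: str
    dfg_phe: tuple[str, int]          # residue carrying CZ
    beta3_lys: tuple[str, int]        # residue carrying CA for D2
    alphac_anchor: tuple[str, int]    # residue carrying CA for D1
    aloop_pair: tuple[AtomRef, AtomRef]
    aloop_cutoff: float               # Å; folded iff distance < cutoff
    alphac_helix_range: tuple[int, int]  # inclusive residue-number range
    alphac_chain: str = "A"

    def __post_init__(self) -> None:
        if self.aloop_cutoff <= 0:
            raise ValueError("aloop_cutoff must be positive")
        lo, hi = self.alphac_helix_range
        if hi < lo:
            raise ValueError("empty alphaC helix range")


@dataclass
class CVSpec:
    """Ordered list of pairwise-distance collective variables."""

    pairs: list[tuple[AtomRef, AtomRef]]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("CVSpec needs at least one distance pair")
        if not self.names:
            self.names = [f"cv{i}" for i in range(len(self.pairs))]
        if len(self.names) != len(self.pairs) or len(set(self.names)) != len(self.names):
            raise ValueError("CV labels must be unique and match the pair count")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(eq=False)
class CVTrajectory:
    """frames × d matrix of CV values (Å) with time metadata."""

    values: np.ndarray
    time_step: float = 1.0  # ns per frame
    source_tag: str = "unbiased"
    frame_metadata: list | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CV values contain NaN/Inf")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_cvs(self) -> int:
        return self.values.shape[1]


# threshold defaults follow the Dunbrack spatial-group convention; they are
# configuration, not measured fact
DFG_THRESHOLDS = {"t_in_d1": 11.0, "t_in_d2": 11.0, "t_out_d1": 11.0, "t_out_d2": 14.0}


@dataclass
class ConformationLabel:
    structure_id: str
    dfg_state: str      # in | inter | out
    aloop_state: str    # folded | extended
    d1: float
    d2: float
    aloop_distance: float


def _atom_position(structure: StructureRecord, ref: AtomRef) -> np.ndarray:
    chain, resnum, name = ref
    return structure.get_atom(chain, int(resnum), name).position


def compute_cvs(structure: StructureRecord, spec: CVSpec) -> np.ndarray:
    """Evaluate each CV distance (Å) on one structure."""
    out = np.empty(len(spec))
    for i, (a, b) in enumerate(spec.pairs):
        out[i] = float(np.linalg.norm(_atom_position(structure, a) - _atom_position(structure, b)))
    return out


def dunbrack_coordinates(structure: StructureRecord, rmap: ResidueMap) -> tuple[float, float]:
    """D1 = |Phe-CZ − αC-anchor-CA|, D2 = |Phe-CZ − β3-Lys-CA| in Å."""
    chain_phe, num_phe = rmap.dfg_phe
    chain_anchor, num_anchor = rmap.alphac_anchor
    chain_lys, num_lys = rmap.beta3_lys
    cz = _atom_position(structure, (chain_phe, num_phe, "CZ"))
    anchor_ca = _atom_position(structure, (chain_anchor, num_anchor, "CA"))
    lys_ca = _atom_position(structure, (chain_lys, num_lys, "CA"))
    return float(np.linalg.norm(cz - anchor_ca)), float(np.linalg.norm(cz - lys_ca))


def classify_dfg(d1: float, d2: float, thresholds: dict | None = None) -> str:
    """Dunbrack-style DFG classification from the (D1, D2) coordinates."""
    if d1 < 0 or d2 < 0:
        raise ValueError("distances must be non-negative")
    t = dict(DFG_THRESHOLDS)
    if thresholds:
        t.update(thresholds)
    if d1 <= t["t_in_d1"] and d2 >= t["t_in_d2"]:
        return "in"
    if d1 > t["t_out_d1"] and d2 <= t["t_out_d2"]:
        return "out"
    return "inter"


def aloop_state(structure: StructureRecord, rmap: ResidueMap) -> tuple[float, str]:
    """A-loop pair distance and folded/extended call (folded iff d < cutoff)."""
    a, b = rmap.aloop_pair
    d = float(np.linalg.norm(_atom_position(structure, a) - _atom_position(structure, b)))
    return d, ("folded" if d < rmap.aloop_cutoff else "extended")


def classify_structure(
    structure: StructureRecord, rmap: ResidueMap, thresholds: dict | None = None
) -> ConformationLabel:
    d1, d2 = dunbrack_coordinates(structure, rmap)
    dist, astate = aloop_state(structure, rmap)
    return ConformationLabel(structure.id, classify_dfg(d1, d2, thresholds), astate, d1, d2, dist)


def frame_helix_broken(
    structure: StructureRecord,
    rmap: ResidueMap,
    spacing_window: tuple[float, float] = (4.5, 7.0),
) -> bool:
    """True if any i→i+4 Cα–Cα distance in the αC range leaves the helical window.

    A Cα-geometry criterion (ideal α-helix i,i+4 spacing ≈ 6.2 Å) is used
    rather than hydrogen-bond analysis because decoys carry no hydrogens.
    """
    lo, hi = rmap.alphac_helix_range
    chain = rmap.alphac_chain
    ca = {}
    for a in structure.atoms:
        if a.chain_id == chain and a.atom_name == "CA" and lo <= a.residue_number <= hi:
            ca[a.residue_number] = a.position
    if len(ca) < 5:
        raise StructureError(
            f"alphaC range {lo}-{hi} has only {len(ca)} CA atoms in {structure.id!r}"
        )
    for i in sorted(ca):
        if i + 4 in ca:
            d = float(np.linalg.norm(ca[i] - ca[i + 4]))
            if not (spacing_window[0] <= d <= spacing_window[1]):
                return True
    return False


def helix_broken_fraction(
    traj_structures: Sequence[StructureRecord],
    rmap: ResidueMap,
    spacing_window: tuple[float, float] = (4.5, 7.0),
) -> float:
    """Fraction of frames with a broken αC helix, in [0, 1]."""
    if not traj_structures:
        raise ValueError("empty trajectory")
    broken = sum(frame_helix_broken(s, rmap, spacing_window) for s in traj_structures)
    return broken / len(traj_structures)


# ---------------------------------------------------------------------------
# configuration I/O

def _parse_atom_ref(entry) -> AtomRef:
    chain, resnum, name = entry
    return (str(chain), int(resnum), str(name))


def load_residue_map(path: str | Path) -> ResidueMap:
    """Read a per-kinase residue map from YAML or JSON."""
    raw = _load_config(path)
    return ResidueMap(
        kinase_name=raw["kinase_name"],
        dfg_phe=(str(raw["dfg_phe"][0]), int(raw["dfg_phe"][1])),
        beta3_lys=(str(raw["beta3_lys"][0]), int(raw["beta3_lys"][1])),
        alphac_anchor=(str(raw["alphac_anchor"][0]), int(raw["alphac_anchor"][1])),
        aloop_pair=(
            _parse_atom_ref(raw["aloop_pair"][0]),
            _parse_atom_ref(raw["aloop_pair"][1]),
        ),
        aloop_cutoff=float(raw["aloop_cutoff"]),
        alphac_helix_range=(int(raw["alphac_helix_range"][0]), int(raw["alphac_helix_range"][1])),
        alphac_chain=str(raw.get("alphac_chain", "A")),
    )


def load_cv_spec(path: str | Path) -> CVSpec:
    raw = _load_config(path)
    pairs = [(_parse_atom_ref(p[0]), _parse_atom_ref(p[1])) for p in raw["pairs"]]
    return CVSpec(pairs=pairs, names=list(raw.get("names", [])))


def _load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_cv_table(path: str | Path, values: np.ndarray, names: Sequence[str],
                   ids: Sequence[str] | None = None) -> None:
    """CV matrix as TSV with a header row of CV labels."""
    df = pd.DataFrame(np.atleast_2d(values), columns=list(names))
    if ids is not None:
        df.insert(0, "structure_id", list(ids))
    df.to_csv(path, sep="\t", index=False)


def read_cv_table(path: str | Path) -> tuple[np.ndarray, list[str], list[str] | None]:
    df = pd.read_csv(path, sep="\t")
    ids = None
    if "structure_id" in df.columns:
        ids = df["structure_id"].astype(str).tolist()
        df = df.drop(columns="structure_id")
    return df.to_numpy(float), list(df.columns), ids


def write_classification_report(path: str | Path, labels: Sequence[ConformationLabel]) -> None:
    df = pd.DataFrame(
        [
            {
                "structure_id": l.structure_id,
                "d1": l.d1,
                "d2": l.d2,
                "dfg_state": l.dfg_state,
                "aloop_distance": l.aloop_distance,
                "aloop_state": l.aloop_state,
            }
            for l in labels
        ]
    )
    df.to_csv(path, sep="\t", index=False)
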