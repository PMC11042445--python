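"""Boltzmann ranking of structure ensembles in the latent space.

Each decoy's CV vector is projected to (σ1, σ2) with the mean encoder, binned
on the PMF grid, and assigned the PMF of its bin. Decoys are ranked by
ascending PMF (ties share the smaller rank ordinal). Decoys whose projection
falls in an unsampled bin — or off the grid entirely — carry an infinite PMF
sentinel, receive no rank and can never be selected: the free-energy surface
says nothing about regions the sampling never visited.

Candidate selection keeps structures with PMF strictly below the cutoff
(default 1 kJ/mol), enriching the low-free-energy, holo-like end of the
ensemble.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fes import PMFGrid
from .spib import SpibModel, project

PMF_SELECTION_CUTOFF = 1.0  # kJ/mol


@dataclass
class RankedStructure:
    structure_id: str
    latent: tuple[float, float]
    bin_index: tuple[int, int] | None
    pmf: float                      # kJ/mol; inf = unsampled sentinel
    rank: int | None                # 1-based over finite-PMF structures
    selected: bool = False

    @property
    def sampled(self) -> bool:
        return np.isfinite(self.pmf)


def assign_pmf(
    decoys: Sequence[tuple[str, np.ndarray]],
    model: SpibModel,
    pmf: PMFGrid,
) -> list[RankedStructure]:
    """Project decoy CV vectors, bin them on the PMF grid and rank by PMF.

    ``decoys`` is a list of (id, raw CV vector). Output is id-ordered; ranks
    run 1..m over the finite-PMF structures, ties sharing the smaller ordinal
    (competition ranking). Off-grid or unsampled decoys get a warning and no
    rank.
    """
    ids = [d[0] for d in decoys]
    X = np.stack([np.asarray(d[1], float) for d in decoys])
    latent = project(model, None, X)

    records = []
    for sid, z in zip(ids, latent):
        ij = pmf.bin_index(z)
        value = float("inf") if ij is None else float(pmf.pmf[ij])
        if not np.isfinite(value):
            warnings.warn(
                f"decoy {sid!r} projects to an unsampled region; no rank assigned",
                stacklevel=2,
            )
        records.append(
            RankedStructure(sid, (float(z[0]), float(z[1])), ij, value, rank=None)
        )

    finite = sorted(
        (r for r in records if r.sampled), key=lambda r: (r.pmf, r.structure_id)
    )
    # competition ranking: equal PMFs share the smaller ordinal
    for pos, rec in enumerate(finite):
        if pos > 0 and rec.pmf == finite[pos - 1].pmf:
            rec.rank = finite[pos - 1].rank
        else:
            rec.rank = pos + 1
    order = {sid: i for i, sid in enumerate(ids)}
    records.sort(key=lambda r: order[r.structure_id])
    return records


def select_candidates(
    ranked: Sequence[RankedStructure],
    cutoff: float = PMF_SELECTION_CUTOFF,
) -> list[RankedStructure]:
    """Structures with PMF strictly below the cutoff, in rank order."""
    chosen = [r for r in ranked if r.sampled and r.pmf < cutoff]
    for r in chosen:
        r.selected = True
    return sorted(chosen, key=lambda r: (r.rank, r.structure_id))


def enrichment_report(
    ranked: Sequence[RankedStructure],
    truth_labels: dict[str, bool] | None = None,
) -> dict:
    """Counts, and — given ground-truth holo-like flags — the enrichment.

    The holo-like fraction before selection (over all decoys) is compared
    with the fraction inside the selected set.
    """
    selected = [r for r in ranked if r.selected]
    report = {
        "n_total": len(ranked),
        "n_sampled": sum(r.sampled for r in ranked),
        "n_selected": len(selected),
    }
    if truth_labels is not None:
        n_holo = sum(bool(truth_labels.get(r.structure_id, False)) for r in ranked)
        n_holo_sel = sum(bool(truth_labels.get(r.structure_id, False)) for r in selected)
        report["holo_fraction_before"] = n_holo / len(ranked) if ranked else 0.0
        report["holo_fraction_selected"] = n_holo_sel / len(selected) if selected else 0.0
        report["n_holo_total"] = n_holo
        report["n_holo_selected"] = n_holo_sel
    return report


def write_ranking(path: str | Path, ranked: Sequence[RankedStructure]) -> None:
    pd.DataFrame(
        [
            {
                "structure_id": r.structure_id,
                "sigma1": r.latent[0],
                "sigma2": r.latent[1],
                "bin_i": -1 if r.bin_index is None else r.bin_index[0],
                "bin_j": -1 if r.bin_index is None else r.bin_index[1],
                "pmf_kJ_mol": r.pmf,
                "rank": -1 if r.rank is None else r.rank,
                "selected": r.selected,
            }
            for r in ranked
        ]
    ).to_csv(path, sep="\t", index=False)


def write_report(path: str | Path, report: dict, provenance: dict | None = None) -> None:
    payload = dict(report)
    if provenance:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=2))
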