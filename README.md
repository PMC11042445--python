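# kinrank

Analysis toolkit for selecting druggable kinase conformations out of
AlphaFold-style structure ensembles. Protein kinases switch between an active
DFG-in state (targeted by type I inhibitors) and an inactive "classical
DFG-out" state with a folded activation loop (targeted by type II inhibitors).
Structure-prediction ensembles generated with reduced-MSA sampling contain
both kinds of decoys, but give no thermodynamic ranking; this package supplies
that ranking from molecular-dynamics data.

The pipeline, module by module:

* **structures** — PDB I/O, Kabsch superposition, heavy-atom ligand RMSD of
  docking poses, and pre-filtering of decoy ensembles (Cα RMSD > 7 Å from the
  reference model is discarded).
* **descriptors** — the order parameters: Dunbrack coordinates
  D1 = |Phe-CZ − αC-anchor-Cα|, D2 = |Phe-CZ − β3-Lys-Cα| classifying the DFG
  motif as in / inter / out; a per-kinase activation-loop distance (folded iff
  d < cutoff, e.g. 15 Å for Abl1 N98–R162 Cβ, 10 Å for the DDR1 E110–R191
  pair); the pairwise-distance collective variables (CVs, 14 in the default
  kinase setup); αC-helix integrity per trajectory frame.
* **clustering** — regular-space clustering of CV vectors, k-means in
  (D1, D2) space, and selection of MD seed structures (2 per
  DFG-state × A-loop-state combination → 12 seeds).
* **spib** — a State Predictive Information Bottleneck with a *linear*
  encoder: z = Wx + b + ε learns a 2-D latent reaction-coordinate space
  (σ1, σ2) by predicting the metastable-state label a lag time Δt ahead,
  with iterative label refinement. Includes the variance-based feature filter
  (keep CVs with σ > 0.25·max σ) and lag screening.
* **fes** — free-energy surfaces over (σ1, σ2): WHAM reweighting of 2-D
  umbrella-sampling windows (default 11×11 grid over σ1 ∈ [−0.8, −0.1],
  σ2 ∈ [0, 0.8], k = 1000 kJ/mol per squared latent unit), or direct
  Boltzmann inversion of concatenated unbiased trajectories; windows with a
  broken αC helix in > 20 % of frames are excluded.
* **ranking** — Boltzmann ranking: project each decoy into the latent space,
  assign the PMF of its bin, rank by ascending PMF, and select candidates
  with PMF < 1 kJ/mol. Decoys in unsampled bins are never ranked or selected.
* **synthetic** — seeded generators for everything the tests need: analytic
  2-D model potentials with overdamped Langevin sampling (biased and
  unbiased), linear lifts to 14-D CV space, labeled two-state trajectories
  and toy kinase structures with dial-in descriptor values.

MD engines, structure prediction and docking are out of scope: the toolkit
consumes their outputs (PDB files, CV time series, latent-space
trajectories) and scores their poses.

## Worked example

Rank a synthetic decoy ensemble against a PMF computed from unbiased
sampling of a double-well free-energy surface:

```python
import numpy as np
from kinrank.synthetic import (double_well_potential, simulate_langevin,
                               LangevinConfig, make_embedding,
                               make_decoy_ensemble, lift_to_cvs,
                               make_linear_recovery_model)
from kinrank.fes import unbiased_pmf, KT_300K
from kinrank.ranking import assign_pmf, select_candidates, enrichment_report

kT = KT_300K                                   # 2.494 kJ/mol (300 K)
pot = double_well_potential(kT=kT, depths_kT=(6.0, 3.0))   # unequal basins
emb, off = make_embedding(14, seed=9)          # 2-D latent -> 14 CVs
decoys = make_decoy_ensemble(pot, (12, 12), outliers=6, seed=13,
                             embedding=emb, offset=off)

runs = [simulate_langevin(pot, LangevinConfig(kT=kT, dt=2e-3,
                                              n_steps=200_000, seed=s,
                                              start=tuple(pot.centers[s % 2])))
        for s in range(4)]
grid = unbiased_pmf(runs, bins=30, kT=kT, burn_in=0.1)

latent = np.concatenate(runs)[::10]
model = make_linear_recovery_model(lift_to_cvs(latent, emb, off).values, latent)

ranked = assign_pmf([(d.id, d.cvs) for d in decoys], model, grid)
selected = select_candidates(ranked, cutoff=1.0)   # PMF < 1 kJ/mol
report = enrichment_report(ranked, {d.id: d.truth == "basin0" for d in decoys})
print(report["holo_fraction_before"], "->", report["holo_fraction_selected"])
print([r.structure_id for r in selected])
```

This prints

```
0.4 -> 1.0
['basin0_001', 'basin0_010', 'basin0_011']
```

meaning: decoys from the deeper basin made up 40 % of the ensemble before
selection, but every structure below the 1 kJ/mol PMF cutoff comes from the
deep basin — the ranking enriched the thermodynamically favoured (holo-like)
conformations, and none of the six off-manifold outliers was selected.

The same steps are exposed as a CLI for file-based pipelines:

```sh
kinrank classify *.pdb --residue-map abl1.yaml --out labels.tsv
kinrank windows --out windows.json            # 11x11 umbrella manifest
kinrank wham --manifest windows.json --out pmf
kinrank rank --decoys decoys.tsv --model spib.json --pmf pmf --out ranking.tsv
kinrank select --ranking ranking.tsv --cutoff 1.0 --out selected.tsv
```

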