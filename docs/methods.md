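# Methods

## The problem

Structure-prediction ensembles of protein kinases (e.g. from reduced-MSA
AlphaFold sampling) mix active DFG-in models with rarer inactive DFG-out
models, but carry no information about their relative free energies. The
toolkit ranks such decoys thermodynamically: learn a 2-D latent
reaction-coordinate space from MD collective-variable (CV) data, estimate the
potential of mean force (PMF) over that space, and assign each decoy the PMF
of the latent-space bin it projects into ("Boltzmann ranking"). Decoys below
a PMF cutoff are the candidates passed on to docking.

## Conformational descriptors

The DFG motif is classified in Dunbrack coordinates: D1 is the distance from
the DFG-phenylalanine ζ-carbon to the Cα of an αC-helix anchor residue, D2
the distance to the β3-lysine Cα. Defaults: DFG-in iff D1 ≤ 11 Å and
D2 ≥ 11 Å; DFG-out iff D1 > 11 Å and D2 ≤ 14 Å; everything else "inter".
The numeric cut lines follow the usual spatial-group convention and are
configuration — the classification operators accept arbitrary thresholds.

The activation loop is called **folded** iff one per-kinase inter-residue
distance is strictly below a cutoff (Abl1: N98–R162 Cβ–Cβ < 15 Å; DDR1:
E110–R191 < 10 Å, atoms configurable since the salt-bridge atoms are a
modelling choice). The strict "<" at the boundary is a fixed convention,
tested explicitly.

αC-helix integrity is judged from Cα geometry alone: a frame is broken if
any i→i+4 Cα–Cα distance inside the configured helix range leaves
[4.5, 7.0] Å (ideal α-helix ≈ 6.2 Å). Hydrogen-bond (DSSP-style) criteria
were deliberately avoided because decoys and MD snapshots do not reliably
carry hydrogens. Umbrella windows whose broken-frame ratio exceeds 20 % are
excluded from WHAM.

## Latent reaction coordinates (SPIB)

CVs (pairwise heavy-atom distances; 14 in the default kinase setup) are
first filtered: only CVs whose standard deviation over the concatenated
trajectories exceeds 0.25 of the maximum CV standard deviation are kept, and
the survivors are z-scored. The State Predictive Information Bottleneck then
learns

    z = W x + b + ε,  ε ~ N(0, diag(exp(log_var)))      (linear encoder, 2-D)
    q(y | z) = softmax(D z + d0)                        (state decoder)

by minimizing E[−log q(y_{t+Δt} | z_t)] + β·KL(p(z|x) ‖ N(0, I)) over
(x_t, y_{t+Δt}) pairs that never cross trajectory boundaries. After each
training round every frame is relabeled to argmax_y q(y | μ(x_t)) using the
deterministic mean encoding, emptied states are dropped, and training stops
when fewer than `relabel_tol` of frames change label. At convergence the
surviving states are the metastable states resolvable at the chosen lag and
(σ1, σ2) = μ(x) is the reaction-coordinate projection used everywhere
downstream (projection always uses the mean encoder, never the stochastic
one).

Defaults and why: β = 1e-3 (small, so prediction dominates and the latent
stays informative; the prior mainly regularizes scale), a single softmax
layer as decoder (keeps the latent interpretable and training nearly convex),
Adam with learning rate 5e-3, batch 512, 2 epochs per relabeling round, at
most 30 rounds, relabel_tol = 0.005. The optimizer state is reset when states
are dropped (the decoder changes shape). Training is a pure function of
(data, seed). Lag screening trains one model per lag and reports state
counts, losses and |Pearson r| between each latent coordinate and supplied
physical features (A-loop distance, D1/D2); lag selection is left to the
user, matching practice where the lag is chosen for physical
interpretability. The implementation is plain numpy with hand-written
gradients — the model is a 2×d linear map plus a k×2 softmax, far below the
size where a deep-learning framework pays off.

Initial labels default to regular-space cluster assignments of the CV
vectors; any integer labeling spanning ≥ 2 states works. A single-state
labeling is allowed (with a warning) and trivially converges to one state.

## Free-energy surfaces

**Umbrella sampling + WHAM.** Windows form a uniform grid over the latent
space — by default 11×11 over σ1 ∈ [−0.8, −0.1], σ2 ∈ [0, 0.8] — each with
an isotropic harmonic bias U_w(σ) = ½k‖σ − σ⁰_w‖², k = 1000 kJ/mol per
squared latent unit. (The force constant is printed in kJ/mol/nm² in the
original protocol although the latent coordinates are dimensionless; the
toolkit applies it per squared latent unit and documents the mismatch.)
Each window's MD starts from the candidate structure nearest its center in
latent space. The WHAM equations

    P(b) = Σ_w n_w(b) / Σ_w N_w exp[(f_w − U_w(b))/kT]
    f_w  = −kT ln Σ_b P(b) exp(−U_w(b)/kT)

are iterated from f_w = 0 until max_w|Δf_w| < 1e-7 kJ/mol (at most 1e5
iterations; non-convergence raises). Window free energies are gauge-fixed to
f_0 = 0; the PMF is gauge-invariant. Bias energies are evaluated at bin
centers, so the bin width should stay small against the bias curvature; the
default grid is 40×40 over the sampled range padded by two bin spacings
(the source protocol does not state its bin width, so it is exposed as a
parameter). kT defaults to 2.494 kJ/mol (300 K).

Note that WHAM is a maximum-likelihood combination of windows: duplicating a
window doubles its weight and shifts the finite-sample estimate slightly
(exactly zero shift only when the duplicated histogram is already
self-consistent, e.g. a single window). The PMF is exactly invariant to
window ordering.

**Boltzmann inversion.** Unbiased latent trajectories are concatenated after
a per-trajectory burn-in (default 10 % of frames, matching a 10 ns discard
from 100 ns runs; an absolute frame count may be given) and histogrammed;
PMF(b) = −kT ln(count/total).

Both estimators shift the PMF so its minimum over sampled bins is exactly 0
and mark unsampled bins with a +inf sentinel. Unsampled bins are never
interpolated: a free-energy surface has nothing to say about regions the
sampling never visited, and the ranking must not pretend otherwise.

## Boltzmann ranking

Each decoy's CV vector is filtered, standardized, projected with the mean
encoder and binned. The decoy receives its bin's PMF; ranks run 1..m over
finite-PMF decoys by ascending PMF with competition ranking for ties (sorted
by id for determinism). Selection keeps PMF strictly below the cutoff
(default 1 kJ/mol). Decoys off the grid or in unsampled bins get the
sentinel, no rank, and can never be selected. Every ranking report records
its provenance (estimator, bins, tolerance, seeds), since PMF values and
ranks shift with the sampling setup even when the enrichment effect is
stable.

## Synthetic fixtures: what they emulate, what they don't

The generators provide desk-scale stand-ins for the expensive inputs:

* **Model potentials** — sums of inverted 2-D Gaussian wells plus a weak
  harmonic confinement, with analytic energy, gradient and binned reference
  PMF (computed by sub-bin quadrature of the Boltzmann weight). The default
  double well has two 5 kT wells separated by 4 widths — deep enough for
  metastability, shallow enough that unbiased trajectories cross at desk
  scale. The confinement (2 kT/(separation·width)²) keeps the sampled domain
  compact, ~1.4 latent units, so "off-manifold" points stay off-manifold.
* **Langevin sampler** — overdamped Euler–Maruyama,
  x ← x − ∇U·dt/γ + √(2kT·dt/γ)·η, optionally under a harmonic umbrella
  bias. Overdamped, not underdamped, because only the stationary
  distribution and slow-mode structure matter to these analyses. dt must
  satisfy dt·k_bias/γ < 0.1 (enforced). The discretization biases the
  stationary variance by O(dt·k/γ) — ~1 % at the default settings, inside
  the 5 % equipartition band the tests use.
* **Linear lifts** — x = Aσ + c + noise with orthonormal A embeds a 2-D
  latent trajectory in 14-D CV space, creating data with exactly two slow
  dimensions, mirroring the real situation where few CVs carry the slow
  dynamics.
* **Two-state trajectories** — a hidden Markov chain with Gaussian CV
  emissions; the emitted labels are the ground truth for SPIB recovery.
* **Toy kinase structures** — minimal Cα/Cβ/Cζ geometry with dial-in D1, D2,
  A-loop distance and helix spacing; not a physically plausible protein,
  just enough atoms to exercise every descriptor and the PDB round trip.
* **Decoy ensembles** — basin-restricted Boltzmann samples from each well,
  lifted to CV space, plus outliers placed ≥ 20 well-widths out so they land
  in unsampled bins of any basin-derived PMF.

What passing these tests shows: the estimators (WHAM, Boltzmann inversion,
SPIB, ranking, clustering, geometry) are correct on data whose ground truth
is known exactly. What they do not show: anything about force-field quality,
sampling convergence of real kinase MD, AlphaFold ensemble composition, or
docking accuracy — those live outside the toolkit.

## Numerical choices and degenerate inputs

* Ties break to the lowest index everywhere (cluster picking, window seeds,
  ranking ids) for determinism; every stochastic routine takes an explicit
  seed.
* Regular-space clustering depends on input order by construction; the file
  order is used and documented. CVs are z-scored before clustering by
  default (same units, different scales).
* Kabsch superposition enforces a proper rotation (no reflections); a
  collinear atom selection warns but returns. Fewer than 3 matched atoms is
  an error. Ligand RMSD is heavy-atom, pairs ligand atoms by name, applies
  the protein superposition to the ligand without re-fitting, and is not
  symmetry-corrected.
* The decoy pre-filter keeps RMSD ≤ 7 Å (strictly greater is discarded);
  a window's helix exclusion triggers strictly above 20 %; candidate
  selection is strictly below the PMF cutoff. All three boundary conventions
  are tested.
* Empty trajectories, all-constant CV sets, lags longer than a trajectory,
  k > n in k-means, degenerate window ranges and unparseable PDB files raise
  informative errors rather than propagating NaNs; a non-finite SPIB loss
  aborts with diagnostics.

## Problem sizes in the shipped checks

The test suite and the acceptance script use 1e5 Langevin steps per umbrella
window (9 windows), 1e6 steps for the equipartition check, 1e5-frame
trajectories for SPIB recovery, 30-decoy ensembles for enrichment, and 100
random instances for the clustering and geometry oracles. These sizes give
Monte-Carlo errors comfortably inside the asserted bands while keeping the
whole suite at a couple of minutes on one CPU.

## Known limitations

* WHAM evaluates bias energies at bin centers (no binless/MBAR estimator
  yet; the interface accommodates one later) and reports no statistical
  error bars on the PMF.
* The SPIB encoder is strictly linear; systems whose slow modes are not
  linearly resolvable in the chosen CVs need a richer encoder than this
  implementation provides.
* Ligand RMSD without symmetry correction overestimates the error of poses
  of symmetric ligands.
* Residue maps are user-supplied; the toolkit does not transfer maps between
  kinases by sequence alignment.
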