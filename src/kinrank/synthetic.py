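"""Synthetic fixtures: model potentials, Langevin sampling, toy structures.

Desk-scale surrogates for the expensive inputs of the real pipeline:

* analytic 2-D model potentials (harmonic well, double well, Gaussian
  mixture) with exact energies, gradients and binned reference PMFs;
* overdamped (Brownian) Langevin dynamics, optionally under a harmonic
  umbrella bias — a stand-in for unbiased and umbrella-sampling MD. Only the
  stationary distribution and slow-mode structure matter to the analyses, so
  inertia is deliberately left out;
* linear lifts of 2-D latent trajectories into a higher-dimensional CV space
  (x = A σ + c + noise), creating many-CV inputs with exactly two slow
  dimensions;
* hidden two-state Markov trajectories with Gaussian CV emissions and known
  labels (ground truth for latent-model state recovery);
* toy kinase structures with dial-in D1/D2, A-loop distance and αC spacing
  (minimal Cα/Cβ/Cζ geometry — not a physically plausible protein);
* decoy ensembles drawn from basin-restricted Boltzmann sampling plus
  off-manifold outliers, with ground-truth basin labels retained.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .descriptors import CVTrajectory, ResidueMap
from .structures import Atom, StructureRecord


# ---------------------------------------------------------------------------
# model potentials

@dataclass(eq=False)
class ModelPotential:
    """Sum of inverted 2-D Gaussian wells (plus an optional harmonic term).

    ``centers`` (m×2), ``depths`` (kJ/mol, positive = well depth) and
    ``widths`` (Gaussian σ per well) define U(x) = −Σ_i d_i exp(−‖x−c_i‖² /
    2w_i²) + ½ k_conf ‖x‖² — the confining term keeps trajectories bounded.
    """

    centers: np.ndarray
    depths: np.ndarray
    widths: np.ndarray
    confine_k: float = 0.0
    form: str = "gaussian_mixture"

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, float))
        self.depths = np.atleast_1d(np.asarray(self.depths, float))
        self.widths = np.atleast_1d(np.asarray(self.widths, float))

    def energy(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        diff = x[..., None, :] - self.centers           # (..., m, 2)
        r2 = np.sum(diff**2, axis=-1)                   # (..., m)
        wells = -np.sum(self.depths * np.exp(-r2 / (2 * self.widths**2)), axis=-1)
        if self.confine_k:
            wells = wells + 0.5 * self.confine_k * np.sum(x**2, axis=-1)
        return wells

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        diff = x[..., None, :] - self.centers
        r2 = np.sum(diff**2, axis=-1)
        g = self.depths * np.exp(-r2 / (2 * self.widths**2)) / self.widths**2
        grad = np.sum(g[..., None] * diff, axis=-2)
        if self.confine_k:
            grad = grad + self.confine_k * x
        return grad

    def analytic_pmf(self, edges: tuple[np.ndarray, np.ndarray], kT: float,
                     subgrid: int = 5) -> np.ndarray:
        """Reference binned PMF: −kT ln of the bin-averaged Boltzmann weight,
        shifted to min 0 (matches what perfect sampling would histogram)."""
        e1, e2 = edges
        n1, n2 = len(e1) - 1, len(e2) - 1
        w = np.zeros((n1, n2))
        for i in range(n1):
            xs = np.linspace(e1[i], e1[i + 1], subgrid + 2)[1:-1]
            for j in range(n2):
                ys = np.linspace(e2[j], e2[j + 1], subgrid + 2)[1:-1]
                X, Y = np.meshgrid(xs, ys, indexing="ij")
                pts = np.stack([X.ravel(), Y.ravel()], axis=1)
                area = (e1[i + 1] - e1[i]) * (e2[j + 1] - e2[j])
                w[i, j] = np.mean(np.exp(-self.energy(pts) / kT)) * area
        pmf = -kT * np.log(w)
        return pmf - pmf.min()


def harmonic_potential(k: float = 1.0, center=(0.0, 0.0)) -> ModelPotential:
    """Isotropic harmonic well U = ½ k ‖x − c‖² (as a confined zero-well mixture)."""
    pot = ModelPotential(centers=[center], depths=[0.0], widths=[1.0], confine_k=k,
                         form="harmonic")
    if any(c != 0 for c in center):
        raise ValueError("harmonic_potential only supports a well at the origin")
    return pot


def double_well_potential(
    kT: float = 2.494,
    depths_kT: tuple[float, float] = (5.0, 5.0),
    width: float = 0.5,
    separation_widths: float = 4.0,
    confine_k: float | None = None,
) -> ModelPotential:
    """Two Gaussian wells on the σ1 axis, ``separation_widths`` widths apart.

    The default (two 5 kT wells separated by 4 widths) is deep enough for
    metastability yet shallow enough that desk-scale trajectories cross.
    """
    half = 0.5 * separation_widths * width
    if confine_k is None:
        # keep the sampled domain compact (~1.4 latent-unit sd under the
        # confinement alone) so off-manifold points stay off-manifold
        confine_k = 2.0 * kT / (separation_widths * width) ** 2
    return ModelPotential(
        centers=[(-half, 0.0), (half, 0.0)],
        depths=[depths_kT[0] * kT, depths_kT[1] * kT],
        widths=[width, width],
        confine_k=confine_k,
        form="double_well",
    )


# ---------------------------------------------------------------------------
# Langevin dynamics

@dataclass
class LangevinConfig:
    kT: float = 2.494          # kJ/mol
    friction: float = 1.0      # 1/time
    dt: float = 1e-3           # time
    n_steps: int = 10_000
    seed: int = 0
    start: tuple[float, float] = (0.0, 0.0)
    bias_center: tuple[float, float] | None = None
    bias_k: float = 0.0
    stride: int = 1            # keep every stride-th frame

    def __post_init__(self) -> None:
        if self.bias_k and self.dt * self.bias_k / self.friction >= 0.1:
            raise ValueError(
                "unstable integration: dt * bias_k / friction must be < 0.1"
            )
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def simulate_langevin(potential: ModelPotential, config: LangevinConfig) -> np.ndarray:
    """Overdamped Euler–Maruyama trajectory on a 2-D potential.

    x ← x − (∇U + ∇U_bias) dt/γ + √(2 kT dt/γ) η,  η ~ N(0, I); seeded and
    deterministic. Returns the (n_kept, 2) positions (start point excluded).
    """
    rng = np.random.default_rng(config.seed)
    x = np.asarray(config.start, float).copy()
    a = config.dt / config.friction
    noise_scale = np.sqrt(2 * config.kT * config.dt / config.friction)
    bias_center = (
        None if config.bias_center is None else np.asarray(config.bias_center, float)
    )
    kb = config.bias_k

    n_out = config.n_steps // config.stride
    out = np.empty((n_out, 2))
    noise = rng.standard_normal((config.n_steps, 2))
    grad = potential.gradient
    kept = 0
    for step in range(config.n_steps):
        g = grad(x)
        if bias_center is not None:
            g = g + kb * (x - bias_center)
        x = x - g * a + noise_scale * noise[step]
        if (step + 1) % config.stride == 0:
            out[kept] = x
            kept += 1
    if not np.all(np.isfinite(out)) or np.max(np.abs(out)) > 1e6:
        raise FloatingPointError("trajectory diverged; reduce dt")
    return out


# ---------------------------------------------------------------------------
# lifts and labeled trajectories

def make_embedding(d: int, seed: int = 0, scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Random (d × 2) linear embedding with orthonormal columns, plus an offset."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((d, 2))
    q, _ = np.linalg.qr(A)
    return scale * q[:, :2], rng.uniform(5.0, 15.0, size=d)


def lift_to_cvs(
    latent_traj: np.ndarray,
    embedding: np.ndarray,
    offset: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    time_step: float = 1.0,
    source_tag: str = "synthetic",
) -> CVTrajectory:
    """Lift a 2-D latent trajectory to d-dim CV space: x = A σ + c + noise."""
    latent_traj = np.atleast_2d(np.asarray(latent_traj, float))
    embedding = np.asarray(embedding, float)
    x = latent_traj @ embedding.T + np.asarray(offset, float)
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0.0, noise_sd, size=x.shape)
    return CVTrajectory(values=x, time_step=time_step, source_tag=source_tag)


def make_two_state_trajectory(
    switch_prob: float | tuple[float, float],
    emission_means: np.ndarray,
    emission_sds: np.ndarray | float,
    n_frames: int,
    seed: int = 0,
    time_step: float = 1.0,
) -> tuple[CVTrajectory, np.ndarray]:
    """Hidden 2-state Markov chain with Gaussian CV emissions; labels returned.

    ``emission_means`` is (2, d); ``emission_sds`` a scalar or (2, d).
    """
    p01, p10 = (switch_prob, switch_prob) if np.isscalar(switch_prob) else switch_prob
    means = np.atleast_2d(np.asarray(emission_means, float))
    d = means.shape[1]
    sds = np.broadcast_to(np.asarray(emission_sds, float), (2, d))
    rng = np.random.default_rng(seed)

    labels = np.empty(n_frames, dtype=int)
    state = int(rng.integers(2))
    u = rng.random(n_frames)
    for t in range(n_frames):
        labels[t] = state
        p = p01 if state == 0 else p10
        if u[t] < p:
            state = 1 - state
    values = means[labels] + rng.standard_normal((n_frames, d)) * sds[labels]
    return CVTrajectory(values=values, time_step=time_step, source_tag="two_state"), labels


# ---------------------------------------------------------------------------
# toy structures

TOY_HELIX_RANGE = (200, 215)


def toy_residue_map(aloop_cutoff: float = 15.0) -> ResidueMap:
    """Residue map matching :func:`make_toy_kinase` (Abl1-like numbering)."""
    return ResidueMap(
        kinase_name="toy",
        dfg_phe=("A", 158),
        beta3_lys=("A", 47),
        alphac_anchor=("A", 66),
        aloop_pair=(("A", 98, "CB"), ("A", 162, "CB")),
        aloop_cutoff=aloop_cutoff,
        alphac_helix_range=TOY_HELIX_RANGE,
        alphac_chain="A",
    )


def make_toy_kinase(
    d1: float = 9.0,
    d2: float = 13.0,
    aloop_distance: float = 10.0,
    helix_spacing: float = 6.2,
    structure_id: str = "toy",
) -> StructureRecord:
    """Minimal structure whose descriptors reproduce the requested values.

    Geometry: Phe158-CZ at the origin, the αC anchor Cα at (d1, 0, 0), the
    β3-Lys Cα at (0, d2, 0); the A-loop Cβ pair along z separated by
    ``aloop_distance``; a straight 16-residue "helix" whose Cα atoms are
    spaced so every i→i+4 distance equals ``helix_spacing`` (ideal α-helix
    ≈ 6.2 Å; values outside [4.5, 7] read as broken).
    """
    atoms = [
        Atom("A", 158, "PHE", "CZ", "C", np.array([0.0, 0.0, 0.0])),
        Atom("A", 158, "PHE", "CA", "C", np.array([1.0, 1.0, -1.0])),
        Atom("A", 66, "MET", "CA", "C", np.array([d1, 0.0, 0.0])),
        Atom("A", 47, "LYS", "CA", "C", np.array([0.0, d2, 0.0])),
        Atom("A", 98, "ASN", "CA", "C", np.array([1.2, 0.0, 30.0])),
        Atom("A", 98, "ASN", "CB", "C", np.array([0.0, 0.0, 30.0])),
        Atom("A", 162, "ARG", "CA", "C", np.array([1.2, 0.0, 30.0 + aloop_distance])),
        Atom("A", 162, "ARG", "CB", "C", np.array([0.0, 0.0, 30.0 + aloop_distance])),
    ]
    lo, hi = TOY_HELIX_RANGE
    for i in range(lo, hi + 1):
        z = (i - lo) * helix_spacing / 4.0
        atoms.append(Atom("A", i, "ALA", "CA", "C", np.array([50.0, 50.0, z])))
    return StructureRecord(structure_id, atoms)


# ---------------------------------------------------------------------------
# decoy ensembles and latent-recovery plumbing

@dataclass(eq=False)
class SyntheticDecoy:
    id: str
    cvs: np.ndarray
    truth: str  # "basin0" | "basin1" | "outlier"
    latent: np.ndarray = field(default_factory=lambda: np.zeros(2))


def sample_basin(
    potential: ModelPotential,
    basin_center: Sequence[float],
    n: int,
    kT: float,
    seed: int,
    n_steps: int = 20_000,
) -> np.ndarray:
    """Basin-restricted Boltzmann sampling: a seeded Langevin run started at the
    basin center, keeping the n frames (post burn-in) nearest that basin."""
    traj = simulate_langevin(
        potential,
        LangevinConfig(kT=kT, dt=2e-3, n_steps=n_steps, seed=seed,
                       start=tuple(basin_center)),
    )
    traj = traj[n_steps // 10 :]
    d_own = np.linalg.norm(traj - np.asarray(basin_center), axis=1)
    others = [c for c in potential.centers if not np.allclose(c, basin_center)]
    in_basin = traj[
        d_own < (np.min([np.linalg.norm(traj - c, axis=1) for c in others], axis=0)
                 if others else np.inf)
    ]
    if len(in_basin) < n:
        raise ValueError("not enough in-basin samples; increase n_steps")
    idx = np.linspace(0, len(in_basin) - 1, n).astype(int)
    return in_basin[idx]


def make_decoy_ensemble(
    potential: ModelPotential,
    n_per_basin: tuple[int, int],
    outliers: int,
    seed: int,
    embedding: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    kT: float = 2.494,
    noise_sd: float = 0.0,
) -> list[SyntheticDecoy]:
    """Decoys from each basin of a two-well potential plus off-manifold outliers.

    Outliers are placed far outside the sampled region (≥ 20 well-widths from
    every well center) so they land in unsampled bins of any PMF built from
    basin samples. Ground truth is retained per decoy.
    """
    if embedding is None or offset is None:
        embedding, offset = make_embedding(14, seed=seed)
    rng = np.random.default_rng(seed)
    decoys: list[SyntheticDecoy] = []
    for b, n in enumerate(n_per_basin):
        if n == 0:
            continue
        pts = sample_basin(potential, potential.centers[b], n, kT, seed + 7 * b + 1)
        for i, z in enumerate(pts):
            x = lift_to_cvs(z, embedding, offset, noise_sd, seed=int(rng.integers(2**31))).values[0]
            decoys.append(SyntheticDecoy(f"basin{b}_{i:03d}", x, f"basin{b}", z))
    width = float(np.max(potential.widths))
    span = float(np.max(np.abs(potential.centers))) + 20 * width
    for i in range(outliers):
        angle = rng.uniform(0, 2 * np.pi)
        z = span * np.array([np.cos(angle), np.sin(angle)]) + potential.centers.mean(axis=0)
        x = lift_to_cvs(z, embedding, offset, noise_sd, seed=int(rng.integers(2**31))).values[0]
        decoys.append(SyntheticDecoy(f"outlier_{i:03d}", x, "outlier", z))
    return decoys


def make_linear_recovery_model(cv_samples: np.ndarray, latent_samples: np.ndarray):
    """Synthetic stand-in latent model: least-squares map from CVs to the true
    latent coordinates, packaged as a fitted filter + linear encoder.

    Used by tests and the acceptance script where the exact latent coordinates
    are known by construction and the question under study is downstream of
    encoder training.
    """
    from .spib import SPIB, FeatureVarianceFilter, SpibModel

    filt = FeatureVarianceFilter(threshold_fraction=0.0).fit(cv_samples)
    Z = filt.transform(cv_samples)
    Zb = np.column_stack([Z, np.ones(len(Z))])
    coef, *_ = np.linalg.lstsq(Zb, np.asarray(latent_samples, float), rcond=None)
    spib = SPIB(lag=1)
    spib.weights_ = coef[:-1].T
    spib.bias_ = coef[-1]
    spib.log_var_ = np.zeros(2)
    spib.decoder_weights_ = np.zeros((1, 2))
    spib.decoder_bias_ = np.zeros(1)
    spib.n_states_ = 1
    spib.n_features_in_ = Z.shape[1]
    return SpibModel(spib=spib, feature_filter=filt)
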