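"""Free-energy surfaces in the 2-D latent space.

Two estimators of the potential of mean force (PMF) over the learnt latent
coordinates (σ1, σ2):

* **WHAM** — self-consistent reweighting of umbrella-sampling windows, each
  biased by an isotropic harmonic U_w(σ) = ½ k ‖σ − σ⁰_w‖². The coupled
  equations

      P(b) = Σ_w n_w(b) / Σ_w N_w exp[(f_w − U_w(b)) / kT]
      f_w  = −kT ln Σ_b P(b) exp(−U_w(b) / kT)

  are iterated from f_w = 0 until max_w |Δf_w| < tol; PMF(b) = −kT ln P(b),
  shifted so the sampled minimum is exactly 0. Window free energies are
  gauge-fixed to f_0 = 0.
* **Boltzmann inversion** — unbiased trajectories are concatenated (after a
  per-trajectory burn-in) and histogrammed; PMF = −kT ln(count / total).

Unsampled bins carry a +inf sentinel and are flagged in ``sampled_mask``;
they are never interpolated, so downstream ranking cannot trust regions the
sampling never visited. The default temperature is 300 K (kT = 2.494 kJ/mol).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

KT_300K = 2.494  # kJ/mol at 300 K
DEFAULT_FORCE_CONSTANT = 1000.0  # kJ/mol per squared latent unit
DEFAULT_WINDOW_SHAPE = (11, 11)
DEFAULT_SIGMA1_RANGE = (-0.8, -0.1)
DEFAULT_SIGMA2_RANGE = (0.0, 0.8)
HELIX_EXCLUSION_THRESHOLD = 0.20


@dataclass(eq=False)
class UmbrellaWindow:
    """One umbrella-sampling window in latent space."""

    id: str
    center: tuple[float, float]
    force_constant: float = DEFAULT_FORCE_CONSTANT
    trajectory: np.ndarray | None = None  # (n, 2) latent series after projection
    burn_in: int = 0                      # frames to discard
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("force_constant must be non-negative")
        if self.trajectory is not None:
            self.trajectory = np.atleast_2d(np.asarray(self.trajectory, float))
            if not self.excluded and self.burn_in >= len(self.trajectory):
                raise ValueError(f"window {self.id}: burn-in consumes the whole trajectory")

    def samples(self) -> np.ndarray:
        if self.trajectory is None:
            raise ValueError(f"window {self.id} has no trajectory")
        return self.trajectory[self.burn_in :]


@dataclass(eq=False)
class PMFGrid:
    """Binned 2-D free-energy surface (kJ/mol, min over sampled bins = 0)."""

    edges: tuple[np.ndarray, np.ndarray]
    pmf: np.ndarray           # (n1, n2), +inf on unsampled bins
    counts: np.ndarray        # (n1, n2) raw sample counts
    kT: float
    sampled_mask: np.ndarray
    window_free_energies: np.ndarray | None = None  # WHAM f_w, gauge f_0 = 0

    def __post_init__(self) -> None:
        assert np.all(np.isfinite(self.pmf[self.sampled_mask]))
        assert np.all(np.isinf(self.pmf[~self.sampled_mask]))
        if self.sampled_mask.any():
            assert abs(self.pmf[self.sampled_mask].min()) < 1e-12

    @property
    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)

    def bin_index(self, point: Sequence[float]) -> tuple[int, int] | None:
        """Bin of a latent point, or None if it falls off the grid."""
        idx = []
        for x, e in zip(point, self.edges):
            if x < e[0] or x > e[-1]:
                return None
            i = int(np.searchsorted(e, x, side="right") - 1)
            idx.append(min(i, len(e) - 2))
        return tuple(idx)

    def lookup(self, point: Sequence[float]) -> float:
        """PMF of the bin containing ``point`` (+inf off-grid or unsampled)."""
        ij = self.bin_index(point)
        return float("inf") if ij is None else float(self.pmf[ij])

    # text serialization: JSON header + columnar TSV of the grid
    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        header = {
            "kT": self.kT,
            "edges_sigma1": self.edges[0].tolist(),
            "edges_sigma2": self.edges[1].tolist(),
            "window_free_energies": None
            if self.window_free_energies is None
            else self.window_free_energies.tolist(),
        }
        prefix.with_suffix(".json").write_text(json.dumps(header))
        i, j = np.meshgrid(
            np.arange(self.pmf.shape[0]), np.arange(self.pmf.shape[1]), indexing="ij"
        )
        pd.DataFrame(
            {
                "bin_i": i.ravel(),
                "bin_j": j.ravel(),
                "pmf_kJ_mol": self.pmf.ravel(),
                "count": self.counts.ravel(),
            }
        ).to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)

    @classmethod
    def load(cls, prefix: str | Path) -> "PMFGrid":
        prefix = Path(prefix)
        header = json.loads(prefix.with_suffix(".json").read_text())
        edges = (
            np.asarray(header["edges_sigma1"], float),
            np.asarray(header["edges_sigma2"], float),
        )
        shape = (len(edges[0]) - 1, len(edges[1]) - 1)
        df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
        pmf = np.full(shape, np.inf)
        counts = np.zeros(shape, int)
        pmf[df["bin_i"], df["bin_j"]] = df["pmf_kJ_mol"]
        counts[df["bin_i"], df["bin_j"]] = df["count"]
        fw = header["window_free_energies"]
        return cls(
            edges=edges,
            pmf=pmf,
            counts=counts,
            kT=float(header["kT"]),
            sampled_mask=np.isfinite(pmf),
            window_free_energies=None if fw is None else np.asarray(fw, float),
        )


def make_window_grid(
    ranges: tuple[tuple[float, float], tuple[float, float]] = (
        DEFAULT_SIGMA1_RANGE,
        DEFAULT_SIGMA2_RANGE,
    ),
    shape: tuple[int, int] = DEFAULT_WINDOW_SHAPE,
    force_constant: float = DEFAULT_FORCE_CONSTANT,
) -> list[UmbrellaWindow]:
    """Uniform grid of umbrella windows, endpoints included on both axes."""
    (lo1, hi1), (lo2, hi2) = ranges
    n1, n2 = shape
    if hi1 <= lo1 or hi2 <= lo2:
        raise ValueError("degenerate window range")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 windows per axis")
    c1 = np.linspace(lo1, hi1, n1)
    c2 = np.linspace(lo2, hi2, n2)
    windows = []
    for i, x in enumerate(c1):
        for j, y in enumerate(c2):
            windows.append(
                UmbrellaWindow(
                    id=f"w{i:02d}_{j:02d}",
                    center=(float(x), float(y)),
                    force_constant=force_constant,
                )
            )
    return windows


def assign_window_seeds(
    windows: Sequence[UmbrellaWindow],
    candidates: Sequence[tuple[str, float, float]],
) -> dict[str, str]:
    """Map each window to the Euclidean-nearest candidate (id, σ1, σ2).

    Each window's simulation starts from the candidate structure closest to
    its equilibrium point; ties break to the lowest candidate index.
    """
    if not candidates:
        raise ValueError("no candidate structures")
    pts = np.array([[c[1], c[2]] for c in candidates], float)
    mapping = {}
    for w in windows:
        d = np.linalg.norm(pts - np.asarray(w.center), axis=1)
        mapping[w.id] = candidates[int(d.argmin())][0]
    return mapping


def bias_energy(window: UmbrellaWindow, point: Sequence[float]) -> float:
    """Isotropic harmonic bias U = ½ k ‖σ − σ⁰‖² in kJ/mol."""
    delta = np.asarray(point, float) - np.asarray(window.center, float)
    return float(0.5 * window.force_constant * np.dot(delta, delta))


def _make_edges(
    windows_or_samples: np.ndarray, bins: int | tuple[int, int] | tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(bins, tuple) and isinstance(bins[0], np.ndarray):
        return bins  # explicit edges
    if isinstance(bins, int):
        bins = (bins, bins)
    lo = windows_or_samples.min(axis=0)
    hi = windows_or_samples.max(axis=0)
    pad = 2.0 * (hi - lo) / np.asarray(bins)
    pad = np.where(pad > 0, pad, 1e-6)
    return (
        np.linspace(lo[0] - pad[0], hi[0] + pad[0], bins[0] + 1),
        np.linspace(lo[1] - pad[1], hi[1] + pad[1], bins[1] + 1),
    )


def _histogram2d(samples: np.ndarray, edges) -> np.ndarray:
    h, _, _ = np.histogram2d(samples[:, 0], samples[:, 1], bins=edges)
    return h


def wham(
    windows: Sequence[UmbrellaWindow],
    bins: int | tuple = 40,
    kT: float = KT_300K,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> PMFGrid:
    """Weighted Histogram Analysis Method on a 2-D latent grid.

    Excluded windows are ignored. ``bins`` is an int, an (n1, n2) pair, or a
    pair of explicit edge arrays; by default the grid covers the union of the
    window samples padded by one bin width. Raises on non-convergence.
    """
    included = [w for w in windows if not w.excluded]
    if not included:
        raise ValueError("no included windows")
    all_samples = np.concatenate([w.samples() for w in included], axis=0)
    if all_samples.size == 0:
        raise ValueError("windows contain no samples")
    edges = _make_edges(all_samples, bins)

    hists = np.stack([_histogram2d(w.samples(), edges) for w in included])  # (W, n1, n2)
    N_w = hists.sum(axis=(1, 2))  # samples per window landing on the grid
    if hists.sum() == 0:
        raise ValueError("no samples fall inside the binning grid")

    c1, c2 = (0.5 * (e[:-1] + e[1:]) for e in edges)
    G1, G2 = np.meshgrid(c1, c2, indexing="ij")
    U = np.stack(
        [
            0.5 * w.force_constant * ((G1 - w.center[0]) ** 2 + (G2 - w.center[1]) ** 2)
            for w in included
        ]
    )  # (W, n1, n2)
    boltz = np.exp(-U / kT)

    numer = hists.sum(axis=0)  # Σ_w n_w(b)
    f = np.zeros(len(included))
    residual_log = []
    for _ in range(max_iter):
        denom = np.tensordot(N_w * np.exp(f / kT), boltz, axes=(0, 0))
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(denom > 0, numer / denom, 0.0)
        Z_w = np.tensordot(boltz, P, axes=([1, 2], [0, 1]))
        f_new = -kT * np.log(Z_w)
        f_new -= f_new[0]  # gauge: f_0 = 0
        resid = float(np.max(np.abs(f_new - f)))
        residual_log.append(resid)
        f = f_new
        if resid < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residual_log[-1]:.3e} kJ/mol)"
        )
    if any(b > a * (1 + 1e-9) for a, b in zip(residual_log[10:], residual_log[11:])):
        warnings.warn("WHAM residual was not monotonically decreasing", stacklevel=2)

    denom = np.tensordot(N_w * np.exp(f / kT), boltz, axes=(0, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(denom > 0, numer / denom, 0.0)
    return _grid_from_probability(P, numer.astype(int), edges, kT, window_free_energies=f)


def unbiased_pmf(
    trajs: Sequence[np.ndarray],
    bins: int | tuple = 40,
    kT: float = KT_300K,
    burn_in: int | float = 0.1,
) -> PMFGrid:
    """Boltzmann inversion of concatenated unbiased latent trajectories.

    ``burn_in`` < 1 is a per-trajectory fraction of frames; >= 1 an absolute
    frame count. PMF = −kT ln(count / total), shifted so the sampled minimum
    is 0.
    """
    if not trajs:
        raise ValueError("no trajectories")
    kept = []
    for t in trajs:
        t = np.atleast_2d(np.asarray(t, float))
        skip = int(burn_in * len(t)) if burn_in < 1 else int(burn_in)
        if skip >= len(t):
            raise ValueError("burn-in consumes an entire trajectory")
        kept.append(t[skip:])
    samples = np.concatenate(kept, axis=0)
    edges = _make_edges(samples, bins)
    counts = _histogram2d(samples, edges)
    if counts.sum() == 0:
        raise ValueError("no samples fall inside the binning grid")
    P = counts / counts.sum()
    return _grid_from_probability(P, counts.astype(int), edges, kT)


def _grid_from_probability(P, counts, edges, kT, window_free_energies=None) -> PMFGrid:
    sampled = P > 0
    pmf = np.full(P.shape, np.inf)
    pmf[sampled] = -kT * np.log(P[sampled])
    pmf[sampled] -= pmf[sampled].min()
    return PMFGrid(
        edges=edges,
        pmf=pmf,
        counts=counts,
        kT=kT,
        sampled_mask=sampled,
        window_free_energies=window_free_energies,
    )


def exclude_windows(
    windows: Sequence[UmbrellaWindow],
    broken_fractions: Sequence[float],
    threshold: float = HELIX_EXCLUSION_THRESHOLD,
) -> list[UmbrellaWindow]:
    """Flag windows whose αC-helix broken-frame ratio strictly exceeds the threshold."""
    if len(windows) != len(broken_fractions):
        raise ValueError("one broken fraction per window required")
    for w, frac in zip(windows, broken_fractions):
        if frac > threshold:
            w.excluded = True
            w.exclusion_reason = (
                f"broken alphaC helix in {frac:.1%} of frames (> {threshold:.0%})"
            )
    return list(windows)


# -- manifest I/O -----------------------------------------------------------

def load_window_manifest(path: str | Path) -> list[UmbrellaWindow]:
    """Windows from a JSON manifest: [{id, center, force_constant, trajectory, burn_in}].

    ``trajectory`` is a path (relative to the manifest) to a TSV with columns
    time_ns, sigma1, sigma2.
    """
    path = Path(path)
    entries = json.loads(path.read_text())
    windows = []
    for e in entries:
        traj = None
        if e.get("trajectory"):
            tpath = Path(e["trajectory"])
            if not tpath.is_absolute():
                tpath = path.parent / tpath
            df = pd.read_csv(tpath, sep="\t")
            traj = df[["sigma1", "sigma2"]].to_numpy(float)
        windows.append(
            UmbrellaWindow(
                id=str(e["id"]),
                center=tuple(e["center"]),
                force_constant=float(e.get("force_constant", DEFAULT_FORCE_CONSTANT)),
                trajectory=traj,
                burn_in=int(e.get("burn_in", 0)),
            )
        )
    return windows


def write_latent_trajectory(path: str | Path, latent: np.ndarray, time_step: float = 1.0) -> None:
    latent = np.atleast_2d(latent)
    pd.DataFrame(
        {
            "time_ns": np.arange(len(latent)) * time_step,
            "sigma1": latent[:, 0],
            "sigma2": latent[:, 1],
        }
    ).to_csv(path, sep="\t", index=False)
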