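"""Clustering of structure ensembles: regular-space, k-means, seed selection.

Regular-space clustering is the sequential rule used to pick well-spread
centers from CV vectors: the first point becomes a center and each later
point becomes one iff it is farther than ``dmin`` from every existing center.
The center set therefore depends on input order (documented; the file order
is used). K-means in Dunbrack (D1, D2) space groups A-loop-folded structures
so the cluster nearest the classical DFG-out reference can be picked out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .descriptors import ConformationLabel


@dataclass(eq=False)
class ClusterResult:
    centers: np.ndarray          # k × d, in the original (unstandardized) space
    assignments: np.ndarray      # n, center index per input point
    dmin: float | None = None
    k: int | None = None
    standardization: tuple[np.ndarray, np.ndarray] | None = None  # (mean, std)

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.n_clusters)


class RegularSpaceClustering(BaseEstimator, ClusterMixin):
    """Sequential regular-space clustering.

    Parameters
    ----------
    dmin : float
        Minimum center-center distance in the clustering metric.
    standardize : bool, default True
        Z-score each dimension before clustering (CVs are all in Å but on
        different scales). Centers are reported in the original space.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (k, d)
    labels_ : ndarray of shape (n,)
        Nearest-center assignment of the training points.
    mean_, scale_ : ndarray of shape (d,)
        Standardization statistics (ones/zeros when standardize=False).
    """

    def __init__(self, dmin: float = 1.0, standardize: bool = True):
        self.dmin = dmin
        self.standardize = standardize

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, float))
        if X.size == 0:
            raise ValueError("empty input")
        if self.dmin <= 0:
            raise ValueError("dmin must be positive")
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            std = X.std(axis=0)
            self.scale_ = np.where(std > 0, std, 1.0)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Z = (X - self.mean_) / self.scale_

        center_idx = [0]
        centers = [Z[0]]
        for i in range(1, len(Z)):
            d = np.linalg.norm(np.asarray(centers) - Z[i], axis=1)
            if np.all(d > self.dmin):
                centers.append(Z[i])
                center_idx.append(i)
        self.center_indices_ = np.asarray(center_idx)
        centers = np.asarray(centers)
        self.cluster_centers_ = centers * self.scale_ + self.mean_
        self.labels_ = self._assign(Z, centers)
        self._centers_std_ = centers
        return self

    @staticmethod
    def _assign(Z: np.ndarray, centers: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(Z[:, None, :] - centers[None, :, :], axis=2)
        return d.argmin(axis=1)

    def predict(self, X):
        Z = (np.atleast_2d(np.asarray(X, float)) - self.mean_) / self.scale_
        return self._assign(Z, self._centers_std_)


def regular_space_cluster(X, dmin: float, standardize: bool = True) -> ClusterResult:
    """Functional wrapper over :class:`RegularSpaceClustering`."""
    est = RegularSpaceClustering(dmin=dmin, standardize=standardize).fit(X)
    return ClusterResult(
        centers=est.cluster_centers_,
        assignments=est.labels_,
        dmin=dmin,
        standardization=(est.mean_, est.scale_),
    )


def kmeans_cluster(X, k: int, seed: int = 0) -> ClusterResult:
    """Lloyd's k-means (k-means++ init, deterministic given seed)."""
    X = np.atleast_2d(np.asarray(X, float))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of points ({len(X)})")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
    return ClusterResult(centers=km.cluster_centers_, assignments=km.labels_, k=k)


def pick_classical_dfg_out_cluster(
    clusters: ClusterResult, reference_point: tuple[float, float]
) -> int:
    """Index of the cluster center nearest the classical-DFG-out reference (D1, D2)."""
    if clusters.n_clusters == 0:
        raise ValueError("no clusters")
    d = np.linalg.norm(clusters.centers - np.asarray(reference_point, float), axis=1)
    best = int(d.argmin())
    if np.sum(np.isclose(d, d[best])) > 1:
        warnings.warn("tie for nearest cluster; picking the lowest index", stacklevel=2)
    return best


def select_seed_structures(
    labels: Sequence[ConformationLabel],
    cluster_result: ClusterResult,
    per_combo: int = 2,
) -> tuple[list[str], dict[tuple[str, str], int]]:
    """Pick seed structures for unbiased MD, ``per_combo`` per conformational class.

    For each of the 6 (DFG in/inter/out × A-loop folded/extended) combinations,
    the candidates nearest their assigned cluster center are chosen. With 2 per
    combination and all 6 populated this yields the 12-structure seed set.
    Under-populated combinations contribute what they have (with a warning).

    Returns (selected ids, inventory of candidates per combination).
    """
    if len(labels) != len(cluster_result.assignments):
        raise ValueError("labels and cluster assignments must align")

    combos = [(d, a) for d in ("in", "inter", "out") for a in ("folded", "extended")]
    dun = np.array([[l.d1, l.d2] for l in labels])
    # distance of each structure to its own cluster center (in the center space)
    centers = cluster_result.centers
    dist_to_center = np.linalg.norm(dun - centers[cluster_result.assignments][:, : dun.shape[1]], axis=1) \
        if centers.shape[1] == dun.shape[1] else np.zeros(len(labels))

    selected: list[str] = []
    inventory: dict[tuple[str, str], int] = {}
    for combo in combos:
        members = [i for i, l in enumerate(labels) if (l.dfg_state, l.aloop_state) == combo]
        inventory[combo] = len(members)
        if not members:
            warnings.warn(f"no candidates for combination {combo}; skipped", stacklevel=2)
            continue
        if len(members) < per_combo:
            warnings.warn(
                f"only {len(members)} candidate(s) for combination {combo}", stacklevel=2
            )
        members.sort(key=lambda i: (dist_to_center[i], i))
        selected.extend(labels[i].structure_id for i in members[:per_combo])
    return selected, inventory
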