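"""Agglomerative hierarchical cluster analysis of autoscaled compounds.

Distances are Euclidean on the autoscaled descriptors.  The default merge
criterion is "incremental" linkage — the name classical chemometrics software
uses for Ward's minimum-variance method, computed through the Lance-Williams
recurrence (heights are reported as distances, not squared distances, so the
similarity scale below is linkage-agnostic).  Complete, single and average
linkage are available as alternatives.

Dendrogram heights can be mapped onto the 0-1 similarity scale customary in
chemometrics dendrograms, ``s = 1 - h / h_max``: identical samples have
similarity 1, the root merge has similarity 0.  Cutting the tree into k
clusters undoes the last k-1 merges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .dataset import QSARDataError

__all__ = [
    "DistanceMatrix",
    "Merge",
    "Dendrogram",
    "LINKAGES",
    "euclidean_distances",
    "agglomerate",
    "to_similarity",
    "cut_clusters",
    "to_newick",
    "merge_table",
]

#: Supported linkage criteria; "incremental" is Ward's minimum-variance method.
LINKAGES = ("incremental", "complete", "single", "average")

_SCIPY_METHOD = {
    "incremental": "ward",
    "complete": "complete",
    "single": "single",
    "average": "average",
}


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal, non-negative

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise QSARDataError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.d)):
            raise QSARDataError("non-finite distances")
        if np.any(self.d < 0):
            raise QSARDataError("negative distances")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise QSARDataError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise QSARDataError("distance matrix diagonal is not zero")


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: the two merged cluster indices (SciPy
    convention: 0..n-1 are leaves, n+step are earlier merges), the linkage
    height and the size of the new cluster."""

    cluster_a: int
    cluster_b: int
    height: float
    new_size: int


@dataclass
class Dendrogram:
    merges: list[Merge]
    leaf_labels: list[str]
    linkage: str
    scale: str = "distance"  # "distance" or "similarity"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])

    def to_scipy(self) -> np.ndarray:
        """The SciPy (n-1) x 4 linkage matrix (distance scale only)."""
        if self.scale != "distance":
            raise QSARDataError("similarity-scaled dendrograms cannot be re-linked")
        return np.array(
            [[m.cluster_a, m.cluster_b, m.height, m.new_size] for m in self.merges],
            dtype=float,
        )


def euclidean_distances(
    scaled_matrix: np.ndarray, labels: list[str] | None = None
) -> DistanceMatrix:
    """Pairwise Euclidean distances between rows of an (autoscaled) matrix."""
    x = np.asarray(scaled_matrix, dtype=float)
    if x.ndim != 2:
        raise QSARDataError("expected a 2-D matrix")
    if not np.all(np.isfinite(x)):
        raise QSARDataError("non-finite entries in input matrix")
    if labels is None:
        labels = [str(i + 1) for i in range(x.shape[0])]
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(labels), d)


def agglomerate(dist: DistanceMatrix, linkage: str = "incremental") -> Dendrogram:
    """Agglomerative clustering of a distance matrix under the given linkage.

    "incremental" applies Ward's minimum-variance update (Lance-Williams
    recurrence); the returned heights are on the distance scale for every
    linkage.  Ties between candidate merges are resolved by SciPy's
    deterministic nearest-neighbor chain order, identical across platforms.
    """
    if linkage not in _SCIPY_METHOD:
        raise QSARDataError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    n = len(dist.labels)
    if n < 2:
        raise QSARDataError("need at least 2 leaves to cluster")
    z = sch.linkage(squareform(dist.d, checks=False), method=_SCIPY_METHOD[linkage])
    merges = [
        Merge(int(a), int(b), float(h), int(size)) for a, b, h, size in z
    ]
    return Dendrogram(merges, list(dist.labels), linkage)


def to_similarity(dendrogram: Dendrogram) -> Dendrogram:
    """Map heights h onto similarities ``s = 1 - h / h_max`` in [0, 1].

    The root merge gets similarity 0 and leaves sit at similarity 1.  If every
    height is zero (all points identical) a warning is issued and all merges
    get similarity 1.
    """
    h = dendrogram.heights()
    h_max = float(h.max(initial=0.0))
    if h_max <= 0.0:
        warnings.warn("all merge heights are zero; similarity set to 1 throughout")
        sims = np.ones_like(h)
    else:
        sims = 1.0 - h / h_max
    merges = [
        Merge(m.cluster_a, m.cluster_b, float(s), m.new_size)
        for m, s in zip(dendrogram.merges, sims)
    ]
    return Dendrogram(merges, list(dendrogram.leaf_labels), dendrogram.linkage, "similarity")


def cut_clusters(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Partition into k clusters by undoing the last k-1 merges.

    Returns label -> cluster id (1-based, numbered by first appearance in
    leaf order).
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise QSARDataError(f"k must lie in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for step, m in enumerate(dendrogram.merges[: n - k]):
        new = n + step
        parent[find(m.cluster_a)] = new
        parent[find(m.cluster_b)] = new

    roots: dict[int, int] = {}
    labels: dict[str, int] = {}
    for i, leaf in enumerate(dendrogram.leaf_labels):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[leaf] = roots[r]
    return labels


def to_newick(dendrogram: Dendrogram) -> str:
    """Serialize as a Newick string with branch lengths from merge heights."""
    tree = sch.to_tree(dendrogram.to_scipy(), rd=False)
    labels = dendrogram.leaf_labels

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = walk(tree.left, tree.dist)
    right = walk(tree.right, tree.dist)
    return f"({left},{right});"


def merge_table(dendrogram: Dendrogram) -> pd.DataFrame:
    """Merge history as a table: ``step,left,right,height,similarity``."""
    sims = to_similarity(dendrogram).heights() if dendrogram.scale == "distance" else None
    rows = []
    for step, m in enumerate(dendrogram.merges):
        rows.append(
            {
                "step": step + 1,
                "left": m.cluster_a,
                "right": m.cluster_b,
                "height": m.height,
                "similarity": float(sims[step]) if sims is not None else m.height,
            }
        )
    return pd.DataFrame(rows)
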