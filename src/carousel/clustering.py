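"""Strategy-class discovery by clustering.

Subsegment feature vectors are z-scored, projected by PCA, and clustered
with Lloyd's K-means initialised by the deterministic Density-K-means++
seeding (density-weighted farthest-point selection, no RNG).  Stability of
the partition across the number of retained principal components and across
k is summarised in a cluster tree (clustree-style shared-member graph) plus
pairwise adjusted-Rand agreement.  Cluster naming is deliberately manual:
the pipeline surfaces exemplar subsegments near each centroid and the user
supplies the cluster -> strategy mapping.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .features import FEATURE_NAMES

__all__ = [
    "ClusterModel",
    "standardize",
    "fit_pca",
    "density_kmeanspp_init",
    "lloyd_kmeans",
    "fit_clusters",
    "build_cluster_tree",
    "exemplars",
    "map_clusters_by_majority",
]


@dataclass
class ClusterModel:
    """Standardisation + PCA + K-means state for one clustering run."""

    centre: np.ndarray | None          # per-feature mean (None for raw scaling)
    scale: np.ndarray | None           # per-feature sd
    components: np.ndarray | None      # PCA loadings, rows orthonormal
    explained_variance_ratio: np.ndarray | None
    n_components: int | None
    k: int = 0
    centroids: np.ndarray = None       # (k, d) in the projected space
    labels: np.ndarray = None          # assignment per row
    inertia: float = math.nan
    n_iter: int = 0

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.centre is not None:
            X = (X - self.centre) / self.scale
        if self.components is not None:
            X = X @ self.components[: self.n_components].T
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self.transform(X)
        return np.argmin(cdist(Z, self.centroids), axis=1)

    def to_json(self, path) -> None:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()
        payload = {
            "centre": arr(self.centre), "scale": arr(self.scale),
            "components": arr(self.components),
            "explained_variance_ratio": arr(self.explained_variance_ratio),
            "n_components": self.n_components, "k": self.k,
            "centroids": arr(self.centroids), "labels": arr(self.labels),
            "inertia": self.inertia, "n_iter": self.n_iter,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        with open(path) as fh:
            d = json.load(fh)
        def arr(a, dtype=float):
            return None if a is None else np.asarray(a, dtype=dtype)
        return cls(
            centre=arr(d["centre"]), scale=arr(d["scale"]),
            components=arr(d["components"]),
            explained_variance_ratio=arr(d["explained_variance_ratio"]),
            n_components=d["n_components"], k=d["k"],
            centroids=arr(d["centroids"]),
            labels=arr(d["labels"], int) if d["labels"] is not None else None,
            inertia=d["inertia"], n_iter=d["n_iter"],
        )


def standardize(X: np.ndarray, mode: str = "zscore"):
    """Per-feature z-scoring (or identity for ``mode="raw"``).

    Returns ``(Z, centre, scale)``; constant features get unit scale.
    """
    X = np.asarray(X, dtype=float)
    if mode == "raw":
        return X, None, None
    if mode != "zscore":
        raise ValueError(f"unknown standardization mode {mode!r}")
    centre = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - centre) / scale, centre, scale


def fit_pca(X: np.ndarray, n_components: int, scaling: str = "zscore") -> ClusterModel:
    """PCA of the (optionally z-scored) feature table.

    All components are retained internally so the explained-variance
    fractions sum to 1; ``n_components`` controls how many the transform
    keeps.
    """
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    if n_components > d:
        raise ValueError(f"n_components={n_components} exceeds dimensionality {d}")
    Z, centre, scale = standardize(X, scaling)
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(Z)
    return ClusterModel(
        centre=centre, scale=scale,
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_components=n_components,
    )


# ---------------------------------------------------------------------------
# Density-K-means++ seeding (deterministic)
# ---------------------------------------------------------------------------

def knn_density(X: np.ndarray, n_neighbors: int | None = None) -> np.ndarray:
    """k-nearest-neighbour density estimate (k = ceil(sqrt(n)) by default):
    the reciprocal of the mean distance to the k nearest neighbours.
    Down-weights outliers, which sit far from everything."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    k = n_neighbors or min(max(1, math.ceil(math.sqrt(n))), n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, _ = nn.kneighbors(X)
    mean_dist = dist[:, 1:].mean(axis=1)  # drop self-distance
    return 1.0 / (mean_dist + 1e-12)


def density_kmeanspp_init(X: np.ndarray, k: int) -> np.ndarray:
    """Deterministic density-weighted farthest-point seeding.

    The first seed is the densest point; each further seed maximises
    ``density * min distance to the seeds chosen so far``.  No randomness:
    repeated runs give identical seeds.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds number of points {n}")
    distinct = len(np.unique(X, axis=0))
    if distinct < k:
        raise ValueError(f"only {distinct} distinct points for k={k}")
    density = knn_density(X)
    chosen = [int(np.argmax(density))]
    min_dist = np.linalg.norm(X - X[chosen[0]], axis=1)
    while len(chosen) < k:
        score = density * min_dist
        score[chosen] = -np.inf
        nxt = int(np.argmax(score))
        chosen.append(nxt)
        min_dist = np.minimum(min_dist, np.linalg.norm(X - X[nxt], axis=1))
    return X[chosen].copy()


def lloyd_kmeans(X: np.ndarray, init: np.ndarray, max_iter: int = 300) -> ClusterModel:
    """Lloyd's alternating assignment/update iteration from explicit seeds.

    Runs until the assignment is a fixed point (or ``max_iter``); inertia is
    non-increasing across iterations.  An emptied cluster is re-seeded with
    the point farthest from its current centroid.
    """
    X = np.asarray(X, dtype=float)
    centroids = np.array(init, dtype=float, copy=True)
    k = len(centroids)
    labels = None
    for it in range(1, max_iter + 1):
        dist = cdist(X, centroids)
        new_labels = np.argmin(dist, axis=1)
        for j in range(k):
            members = new_labels == j
            if members.any():
                centroids[j] = X[members].mean(axis=0)
            else:
                # re-seed with the globally worst-fitted point
                far = int(np.argmax(dist[np.arange(len(X)), new_labels]))
                centroids[j] = X[far]
                new_labels[far] = j
        if labels is not None and np.array_equal(labels, new_labels):
            break
        labels = new_labels
    inertia = float(np.sum((X - centroids[labels]) ** 2))
    return ClusterModel(
        centre=None, scale=None, components=None,
        explained_variance_ratio=None, n_components=None,
        k=k, centroids=centroids, labels=labels, inertia=inertia, n_iter=it,
    )


def fit_clusters(X: np.ndarray, k: int, n_components: int | None = None,
                 scaling: str = "zscore") -> ClusterModel:
    """Standardise, project, and cluster a feature table in one call."""
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    n_components = n_components or d
    model = fit_pca(X, n_components, scaling)
    Z = model.transform(X)
    km = lloyd_kmeans(Z, density_kmeanspp_init(Z, k))
    model.k = k
    model.centroids = km.centroids
    model.labels = km.labels
    model.inertia = km.inertia
    model.n_iter = km.n_iter
    return model


# ---------------------------------------------------------------------------
# Cluster tree and stability
# ---------------------------------------------------------------------------

def build_cluster_tree(X: np.ndarray, k_range=range(1, 11), pc_range=range(2, 12),
                       scaling: str = "zscore"):
    """Cluster trees across k for each PC count, plus a stability report.

    Returns ``(trees, stability)``.  ``trees`` maps each PC count to a
    directed shared-member graph: nodes ``(k, cluster)`` carry their size,
    edges between consecutive k levels carry the number of shared members
    (outgoing weights of a node sum to its size).  ``stability`` is a tidy
    frame of adjusted Rand indices between every pair of PC settings at each
    k.
    """
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    pc_range = [p for p in pc_range if p <= d]
    partitions: dict[int, dict[int, np.ndarray]] = {}
    trees: dict[int, nx.DiGraph] = {}
    for pc in pc_range:
        partitions[pc] = {}
        for k in k_range:
            partitions[pc][k] = fit_clusters(X, k, n_components=pc, scaling=scaling).labels
        tree = nx.DiGraph()
        ks = sorted(partitions[pc])
        for k in ks:
            lab = partitions[pc][k]
            for c in range(k):
                tree.add_node((k, c), k=k, cluster=c, size=int(np.sum(lab == c)))
        for k_prev, k_next in zip(ks[:-1], ks[1:]):
            prev, nxt = partitions[pc][k_prev], partitions[pc][k_next]
            for c_prev in range(k_prev):
                members = prev == c_prev
                for c_next in range(k_next):
                    shared = int(np.sum(members & (nxt == c_next)))
                    if shared:
                        tree.add_edge((k_prev, c_prev), (k_next, c_next), weight=shared)
        trees[pc] = tree
    rows = []
    for k in k_range:
        for i, pa in enumerate(pc_range):
            for pb in pc_range[i + 1:]:
                rows.append({
                    "k": k, "pc_a": pa, "pc_b": pb,
                    "ari": adjusted_rand_score(partitions[pa][k], partitions[pb][k]),
                })
    return trees, pd.DataFrame(rows)


def exemplars(model: ClusterModel, X: np.ndarray, n: int = 5) -> dict[int, np.ndarray]:
    """Indices of the ``n`` members nearest each centroid, per cluster,
    ordered by distance (whole cluster if smaller than ``n``)."""
    Z = model.transform(X)
    out = {}
    for c in range(model.k):
        members = np.flatnonzero(model.labels == c)
        dist = np.linalg.norm(Z[members] - model.centroids[c], axis=1)
        order = members[np.argsort(dist, kind="stable")]
        out[c] = order[:n]
    return out


def map_clusters_by_majority(cluster_labels: np.ndarray, true_labels) -> dict[int, str]:
    """Cluster -> class mapping by plurality of ground-truth labels.

    Convenience for synthetic benchmarks where ground truth exists; real
    analyses supply the mapping manually after inspecting exemplars.
    """
    cluster_labels = np.asarray(cluster_labels)
    true_labels = np.asarray(true_labels)
    mapping = {}
    for c in np.unique(cluster_labels):
        values, counts = np.unique(true_labels[cluster_labels == c], return_counts=True)
        mapping[int(c)] = str(values[np.argmax(counts)])
    return mapping


def plot_exemplars(model: ClusterModel, segments, X, n: int = 5, path=None):
    """Panel figure of exemplar subsegments per cluster, room frame on the
    left and arena frame on the right of each cell."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ex = exemplars(model, X, n)
    fig, axes = plt.subplots(model.k, 2, figsize=(7, 2.6 * model.k), squeeze=False)
    for c in range(model.k):
        for col, frame in enumerate(("room", "arena")):
            ax = axes[c][col]
            for idx in ex[c]:
                seg = segments[int(idx)]
                x, y = seg.xy_room() if frame == "room" else seg.xy_arena()
                ax.plot(x, y, lw=0.8)
            R = segments[0].config.radius
            circle = plt.Circle((0, 0), R, fill=False, color="grey", lw=0.8)
            ax.add_patch(circle)
            ax.set_aspect("equal")
            ax.set_xlim(-1.1 * R, 1.1 * R)
            ax.set_ylim(-1.1 * R, 1.1 * R)
            ax.set_title(f"cluster {c} ({frame})", fontsize=8)
            ax.set_xticks([]); ax.set_yticks([])
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
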