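"""Evaluation metrics for integration and trajectory quality.

All scores assume ground-truth information that only matched (e.g.,
simulated) data provides: cell-cell correspondence across modalities, true
branch labels, true pseudotime, or true expression profiles.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from scipy.stats import kendalltau
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .trajectory import leiden_cluster

__all__ = [
    "neighborhood_overlap",
    "cosine_matching_score",
    "branch_f1",
    "pseudotime_kendall",
    "kmeans_matching_ari",
    "cluster_ari_scan",
    "graph_connectivity",
    "normalized_mse",
]


def neighborhood_overlap(Z_a: np.ndarray, Z_b: np.ndarray,
                         matching: np.ndarray, k: int) -> float:
    """Fraction of matched cells found within each other's k-neighborhood.

    The kNN graph is built on the pooled embedding of both batches; matching
    is an (m, 2) array of (row in Z_a, row in Z_b) index pairs.
    """
    Z_a, Z_b = np.asarray(Z_a, float), np.asarray(Z_b, float)
    pooled = np.vstack([Z_a, Z_b])
    if k >= pooled.shape[0]:
        raise ValueError("k must be smaller than the pooled cell count")
    matching = np.asarray(matching)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pooled)
    _, idx = nn.kneighbors(pooled)
    idx = idx[:, 1:]
    off = Z_a.shape[0]
    hits = 0
    for ia, ib in matching:
        if (ib + off) in idx[ia] or ia in idx[ib + off]:
            hits += 1
    return hits / len(matching)


def cosine_matching_score(Z_a: np.ndarray, Z_b: np.ndarray,
                          matching: np.ndarray) -> float:
    """Mean cosine similarity over matched embedding pairs."""
    Z_a, Z_b = np.asarray(Z_a, float), np.asarray(Z_b, float)
    matching = np.asarray(matching)
    za = Z_a[matching[:, 0]]
    zb = Z_b[matching[:, 1]]
    na = np.linalg.norm(za, axis=1)
    nb = np.linalg.norm(zb, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        bad = int(np.argmin(np.minimum(na, nb)))
        raise ValueError(f"zero-norm embedding for matched pair {bad}")
    return float(np.mean((za * zb).sum(axis=1) / (na * nb)))


def _jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b)


def branch_f1(true_branches: np.ndarray, inferred_branches: np.ndarray) -> float:
    """Harmonic mean of Jaccard-based recovery and relevance between the true
    and inferred branch partitions of the same cells."""
    true_branches = np.asarray(true_branches)
    inferred_branches = np.asarray(inferred_branches)
    if true_branches.size == 0 or true_branches.shape != inferred_branches.shape:
        raise ValueError("branch partitions must be nonempty and aligned")
    t_sets = [set(np.flatnonzero(true_branches == b))
              for b in np.unique(true_branches)]
    i_sets = [set(np.flatnonzero(inferred_branches == b))
              for b in np.unique(inferred_branches)]
    J = np.array([[_jaccard(t, i) for i in i_sets] for t in t_sets])
    recovery = J.max(axis=1).mean()
    relevance = J.max(axis=0).mean()
    if recovery == 0 or relevance == 0:
        return 0.0
    return float(2.0 / (1.0 / recovery + 1.0 / relevance))


def pseudotime_kendall(t_true: np.ndarray, t_inferred: np.ndarray) -> float:
    """Kendall tau-b rank correlation between true and inferred pseudotime."""
    t_true = np.asarray(t_true, float)
    t_inferred = np.asarray(t_inferred, float)
    if t_true.size < 2 or t_true.shape != t_inferred.shape:
        raise ValueError("need two aligned vectors of length >= 2")
    if np.ptp(t_true) == 0 or np.ptp(t_inferred) == 0:
        raise ValueError("constant pseudotime vector: correlation undefined")
    tau, _ = kendalltau(t_true, t_inferred)
    return float(tau)


def kmeans_matching_ari(Z_a: np.ndarray, Z_b: np.ndarray,
                        matching: np.ndarray, n_clusters: int,
                        seed: int = 0) -> float:
    """ARI between per-modality k-means labels aligned by the matching."""
    Z_a, Z_b = np.asarray(Z_a, float), np.asarray(Z_b, float)
    if n_clusters > min(Z_a.shape[0], Z_b.shape[0]):
        raise ValueError("n_clusters exceeds the number of cells")
    matching = np.asarray(matching)
    la = KMeans(n_clusters, random_state=seed, n_init=10).fit_predict(Z_a)
    lb = KMeans(n_clusters, random_state=seed, n_init=10).fit_predict(Z_b)
    return float(adjusted_rand_score(la[matching[:, 0]], lb[matching[:, 1]]))


def cluster_ari_scan(Z_all: np.ndarray, true_labels: np.ndarray,
                     resolutions=(0.1, 0.6), seed: int = 0) -> float:
    """Best ARI of Leiden labels vs truth over the resolution grid
    (0.1 to 1 with step 0.5 by default, i.e. {0.1, 0.6})."""
    true_labels = np.asarray(true_labels)
    best = -1.0
    for res in resolutions:
        labels = leiden_cluster(Z_all, resolution=res, seed=seed)
        best = max(best, float(adjusted_rand_score(true_labels, labels)))
    return best


def graph_connectivity(Z_all: np.ndarray, cell_type_labels: np.ndarray,
                       k: int = 15) -> float:
    """Mean over cell types of the largest-connected-component fraction of
    the type-induced subgraph of the pooled kNN graph; measures mixing."""
    Z_all = np.asarray(Z_all, float)
    labels = np.asarray(cell_type_labels)
    n = Z_all.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the cell count")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z_all)
    A = nn.kneighbors_graph(Z_all, mode="connectivity")
    A = A + A.T  # symmetrize
    scores = []
    for t in np.unique(labels):
        idx = np.flatnonzero(labels == t)
        sub = A[np.ix_(idx, idx)]
        ncomp, comp = connected_components(sub, directed=False)
        largest = np.bincount(comp).max()
        scores.append(largest / idx.size)
    return float(np.mean(scores))


def normalized_mse(X_pred: np.ndarray, X_true: np.ndarray) -> float:
    """Mean squared distance between row-unit-normalized true and predicted
    profiles; scale-invariant per cell, bounded by 4."""
    X_pred = np.asarray(X_pred, float)
    X_true = np.asarray(X_true, float)
    if X_pred.shape != X_true.shape:
        raise ValueError("shape mismatch")
    np_ = np.linalg.norm(X_pred, axis=1)
    nt = np.linalg.norm(X_true, axis=1)
    if np.any(np_ == 0) or np.any(nt == 0):
        bad = int(np.argmin(np.minimum(np_, nt)))
        raise ValueError(f"zero-norm row at cell {bad}")
    diff = X_true / nt[:, None] - X_pred / np_[:, None]
    return float(np.mean((diff ** 2).sum(axis=1)))
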