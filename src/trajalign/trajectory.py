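"""Trajectory inference on the integrated latent space.

Backbone: Leiden clustering of a kNN graph of the joint embedding (coarse
resolution: the backbone should have roughly one cluster per trajectory
segment), then a minimum spanning tree over the fully connected
cluster-centroid graph weighted by Euclidean distance. Pseudotime: diffusion
distance from a root cell on the joint embedding (diffusion distance orders
cells along the manifold, so it doubles as pseudotime), min-max scaled to
[0, 1]. Branches: maximal backbone path segments between nodes of
degree != 2, rooted at the root cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
from sklearn.neighbors import NearestNeighbors

from .diffusion import adaptive_kernel, diffusion_distance

__all__ = [
    "TrajectoryResult",
    "leiden_cluster",
    "infer_backbone",
    "infer_pseudotime",
    "assign_branches",
    "infer_trajectory",
]


@dataclass
class TrajectoryResult:
    cluster_labels: np.ndarray
    centroids: np.ndarray
    backbone_edges: list[tuple[int, int, float]]
    root: int  # root cell index
    pseudotime: np.ndarray | None = None
    branch_labels: np.ndarray | None = None


def _knn_graph(Z: np.ndarray, k: int) -> igraph.Graph:
    n = Z.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z)
    _, idx = nn.kneighbors(Z)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=n, edges=sorted(edges))
    return g


def leiden_cluster(Z: np.ndarray, resolution: float = 1.0, k: int = 15,
                   seed: int = 0) -> np.ndarray:
    """Leiden community labels on a kNN graph of the embedding."""
    g = _knn_graph(np.asarray(Z, float), k)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed)
    return np.asarray(part.membership)


def _kruskal(n: int, weights: dict[tuple[int, int], float]
             ) -> list[tuple[int, int, float]]:
    """MST by Kruskal; ties broken lexicographically on (weight, i, j)."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst = []
    for (i, j), w in sorted(weights.items(), key=lambda kv: (kv[1], kv[0])):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            mst.append((i, j, w))
    return mst


def infer_backbone(Z_all: np.ndarray, resolution: float = 0.3,
                   seed: int = 0, k: int = 15) -> TrajectoryResult:
    """Cluster the joint embedding and span the centroids with an MST."""
    Z_all = np.asarray(Z_all, float)
    if Z_all.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    labels = leiden_cluster(Z_all, resolution=resolution, k=k, seed=seed)
    n_clusters = labels.max() + 1
    centroids = np.vstack([Z_all[labels == c].mean(axis=0)
                           for c in range(n_clusters)])
    if n_clusters == 1:
        warnings.warn("single cluster: empty backbone")
        return TrajectoryResult(labels, centroids, [], root=0)
    weights = {(i, j): float(np.linalg.norm(centroids[i] - centroids[j]))
               for i in range(n_clusters) for j in range(i + 1, n_clusters)}
    mst = _kruskal(n_clusters, weights)
    return TrajectoryResult(labels, centroids, mst, root=0)


def infer_pseudotime(Z_all: np.ndarray, root: int, k_nn: int = 30,
                     alpha: float = 2.0, t_list=(30, 50, 70)) -> np.ndarray:
    """Diffusion distance from the root cell, min-max scaled to [0, 1].

    The kernel defaults differ from the input-space geometry (k_nn=5,
    alpha=40): a low-dimensional trained embedding is far more compact than
    raw count data, and the near-binary sharp kernel fragments it; a wide
    Gaussian kernel (alpha=2) over a larger neighborhood keeps the random
    walk connected along the trajectory.
    """
    Z_all = np.asarray(Z_all, float)
    if not 0 <= root < Z_all.shape[0]:
        raise ValueError(f"root index {root} out of range")
    K = adaptive_kernel(Z_all, k_nn=k_nn, alpha=alpha)
    geom = diffusion_distance(K, t_list=t_list)
    t = geom.D[root].copy()
    rng_ = t.max() - t.min()
    if rng_ <= 0:
        raise ValueError(
            "degenerate pseudotime (disconnected kernel graph?); "
            "try a larger k_nn")
    return (t - t.min()) / rng_


def assign_branches(traj: TrajectoryResult, root_cluster: int | None = None
                    ) -> np.ndarray:
    """Label each cell by its backbone branch.

    The MST is rooted at the root cluster; a branch is a maximal root-to-leaf
    path segment between nodes of degree != 2 (branchings and endpoints).
    """
    labels = traj.cluster_labels
    n_clusters = int(labels.max()) + 1
    if root_cluster is None:
        root_cluster = int(labels[traj.root])
    if not traj.backbone_edges:
        return np.zeros_like(labels)
    adj: dict[int, list[int]] = {c: [] for c in range(n_clusters)}
    for i, j, _ in traj.backbone_edges:
        adj[i].append(j)
        adj[j].append(i)
    deg = {c: len(adj[c]) for c in adj}
    # Walk from the root; a segment ends at any node of degree != 2, so a new
    # branch starts at the root and below every branching (degree >= 3) node,
    # which the incoming segment keeps.
    branch_of = np.full(n_clusters, -1)
    next_branch = 0
    stack = [(root_cluster, -1, None)]  # (node, parent, current branch)
    while stack:
        node, parent, br = stack.pop()
        if br is None or deg.get(parent, 0) > 2:
            br = next_branch
            next_branch += 1
        branch_of[node] = br
        for nb in sorted(adj[node]):
            if nb != parent:
                stack.append((nb, node, br))
    branch_of[branch_of < 0] = next_branch  # clusters off the tree (shouldn't happen)
    return branch_of[labels]


def infer_trajectory(Z_all: np.ndarray, root: int, resolution: float = 0.3,
                     seed: int = 0, k: int = 15) -> TrajectoryResult:
    """Backbone + pseudotime + branch labels in one call."""
    traj = infer_backbone(Z_all, resolution=resolution, seed=seed, k=k)
    traj.root = root
    traj.pseudotime = infer_pseudotime(Z_all, root)
    traj.branch_labels = assign_branches(traj)
    return traj
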