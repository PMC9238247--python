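"""Mutual-nearest-neighbor smoothing of the trained embeddings.

Cells that are mutual k-nearest neighbors across modalities are pulled onto
the Gaussian-weighted mean of their cross-modality neighbors, which tightens
the shared trajectory; cells with no mutual neighbor keep their embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["MnnGraph", "build_mnn_graph", "refine_embedding", "refine_all_pairs"]


@dataclass
class MnnGraph:
    """Directed cross-modality edges i (batch A) -> j (batch B) with weights."""

    edges_ab: list[tuple[int, int, float]]  # (i in A, j in B, weight)
    edges_ba: list[tuple[int, int, float]]
    k: int


def _knn_sets(D: np.ndarray, k: int) -> list[set]:
    """Row-wise k nearest columns of a rectangular distance matrix."""
    idx = np.argsort(D, axis=1, kind="stable")[:, :k]
    return [set(row) for row in idx]


def build_mnn_graph(Z_a: np.ndarray, Z_b: np.ndarray, k: int = 10) -> MnnGraph:
    """Mutual kNN graph between two embeddings of the same latent space.

    Edge (i, j) exists iff j is among i's k nearest cells in Z_b AND i is
    among j's k nearest cells in Z_a; weight exp(-||z_a(i) - z_b(j)||^2).
    """
    Z_a, Z_b = np.asarray(Z_a, float), np.asarray(Z_b, float)
    if Z_a.shape[1] != Z_b.shape[1]:
        raise ValueError("latent dimensions differ")
    kmax = min(Z_a.shape[0], Z_b.shape[0])
    if k >= kmax + 1 and k > kmax:
        warnings.warn(f"k={k} clipped to batch size {kmax}")
        k = kmax
    D = cdist(Z_a, Z_b)
    nn_ab = _knn_sets(D, k)        # for each i in A: its k nearest in B
    nn_ba = _knn_sets(D.T, k)      # for each j in B: its k nearest in A
    edges_ab, edges_ba = [], []
    for i, js in enumerate(nn_ab):
        for j in js:
            if i in nn_ba[j]:
                w = float(np.exp(-D[i, j] ** 2))
                edges_ab.append((i, j, w))
                edges_ba.append((j, i, w))
    return MnnGraph(edges_ab, edges_ba, k)


def _smooth(Z_self: np.ndarray, Z_other: np.ndarray,
            edges: list[tuple[int, int, float]]) -> np.ndarray:
    out = Z_self.copy()
    num = np.zeros_like(Z_self)
    den = np.zeros(Z_self.shape[0])
    for i, j, w in edges:
        num[i] += w * Z_other[j]
        den[i] += w
    has = den > 0
    out[has] = num[has] / den[has, None]
    return out


def refine_embedding(Z_a: np.ndarray, Z_b: np.ndarray,
                     graph: MnnGraph | None = None,
                     k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """One pass of MNN smoothing, applied symmetrically from the pre-update
    embeddings. Isolated cells are left in place."""
    Z_a, Z_b = np.asarray(Z_a, float), np.asarray(Z_b, float)
    if graph is None:
        graph = build_mnn_graph(Z_a, Z_b, k=k)
    return _smooth(Z_a, Z_b, graph.edges_ab), _smooth(Z_b, Z_a, graph.edges_ba)


def refine_all_pairs(Z_list: list[np.ndarray], k: int = 10) -> list[np.ndarray]:
    """Pairwise MNN smoothing for any number of batches.

    Every pair is smoothed from the original embeddings and each cell's
    updates are averaged, which makes the result independent of pair order.
    """
    n = len(Z_list)
    if n == 1:
        return [Z.copy() for Z in Z_list]
    acc = [np.zeros_like(Z) for Z in Z_list]
    cnt = [0] * n
    for a in range(n):
        for b in range(a + 1, n):
            Za_new, Zb_new = refine_embedding(Z_list[a], Z_list[b], k=k)
            acc[a] += Za_new
            acc[b] += Zb_new
            cnt[a] += 1
            cnt[b] += 1
    return [acc[i] / cnt[i] for i in range(n)]
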