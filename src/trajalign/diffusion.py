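"""Diffusion geometry of a single batch: the trajectory-manifold distances
that the latent space is trained to preserve.

Pipeline per batch: linear dimension reduction (PCA for RNA, TF-IDF + LSI for
ATAC) -> adaptive-bandwidth similarity kernel -> row-stochastic transition
matrix -> averaged multi-scale diffusion operator -> pairwise diffusion
distances D and the normalized distribution Q = D / sum(D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA, TruncatedSVD

from .io import OmicsBatch

__all__ = [
    "ReducedRepresentation",
    "DiffusionGeometry",
    "reduce_dimension",
    "adaptive_kernel",
    "diffusion_distance",
    "distance_distribution",
    "batch_geometry",
]

DEFAULT_T_LIST = (30, 50, 70)


@dataclass
class ReducedRepresentation:
    coords: np.ndarray  # cells x r
    method: str         # "PCA" or "LSI"
    r: int


@dataclass
class DiffusionGeometry:
    K: np.ndarray       # adaptive similarity kernel
    P: np.ndarray       # row-stochastic transition matrix
    P_bar: np.ndarray   # norm-averaged diffused operator
    D: np.ndarray       # diffusion distance matrix
    Q: np.ndarray       # D normalized to total mass 1
    params: dict = field(default_factory=dict)


def tfidf(X: np.ndarray) -> np.ndarray:
    """TF-IDF weighting of a binary accessibility matrix.

    tf = x / rowsum; idf = log(1 + n_cells / df). All-zero columns get idf 0.
    """
    X = np.asarray(X, dtype=float)
    rs = X.sum(axis=1, keepdims=True)
    if np.any(rs == 0):
        raise ValueError("cell with no accessible regions")
    tf = X / rs
    df = X.astype(bool).sum(axis=0)
    idf = np.where(df > 0, np.log(1.0 + X.shape[0] / np.maximum(df, 1)), 0.0)
    return tf * idf


def reduce_dimension(batch: OmicsBatch, r: int = 30,
                     drop_first_lsi: bool = False) -> ReducedRepresentation:
    """PCA of centered log-normalized RNA, or LSI (TF-IDF + truncated SVD) of
    binary ATAC. r is clipped only by an explicit error, never silently."""
    if r < 2:
        raise ValueError("r must be >= 2")
    X = batch.dense()
    max_r = min(X.shape) - (1 if batch.modality == "RNA" else 0)
    if r > max_r:
        raise ValueError(f"r={r} exceeds usable rank {max_r} for this batch")
    if batch.modality == "RNA":
        coords = PCA(n_components=r, random_state=0).fit_transform(X)
        return ReducedRepresentation(coords, "PCA", r)
    W = tfidf(X)
    svd = TruncatedSVD(n_components=r + (1 if drop_first_lsi else 0),
                       random_state=0)
    coords = svd.fit_transform(W)
    if drop_first_lsi:
        coords = coords[:, 1:]
    return ReducedRepresentation(coords, "LSI", r)


def adaptive_kernel(coords: np.ndarray, k_nn: int = 5,
                    alpha: float = 40.0) -> np.ndarray:
    """Adaptive-bandwidth similarity kernel.

    K(i,j) = 1/2 exp(-(d_ij/sigma_i)^alpha) + 1/2 exp(-(d_ij/sigma_j)^alpha)
    with sigma_i the distance from cell i to its k_nn-th nearest neighbor.
    The large alpha makes the kernel an approximate indicator of the k-NN ball,
    which keeps the random walk on the trajectory manifold.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < k_nn + 1:
        raise ValueError(f"need at least k_nn+1={k_nn + 1} cells, got {n}")
    dist = squareform(pdist(coords))
    sigma = np.sort(dist, axis=1)[:, k_nn]  # column 0 is the self-distance
    if np.any(sigma == 0):
        pos = np.where(dist > 0, dist, np.inf)
        fallback = pos.min(axis=1)
        if not np.all(np.isfinite(fallback[sigma == 0])):
            raise ValueError("all cells identical; kernel bandwidth undefined")
        sigma = np.where(sigma == 0, fallback, sigma)
    with np.errstate(over="ignore"):
        Ei = np.exp(-np.power(dist / sigma[:, None], alpha))
    K = 0.5 * (Ei + Ei.T)
    np.fill_diagonal(K, 1.0)
    return K


def _averaged_operator(P: np.ndarray, t_list=DEFAULT_T_LIST,
                       norm: str = "fro") -> np.ndarray:
    """sum_t P^t / ||P^t||, powers by repeated squaring."""
    t_list = sorted(t_list)
    powers = {}
    # binary powering with a cache of P^(2^k)
    sq = {1: P}
    def power(t):
        out = None
        k, b = t, 1
        while k:
            if b not in sq:
                sq[b] = sq[b // 2] @ sq[b // 2]
            if k & 1:
                out = sq[b] if out is None else out @ sq[b]
            k >>= 1
            b <<= 1
        return out
    acc = np.zeros_like(P)
    for t in t_list:
        Pt = power(t)
        powers[t] = Pt
        nrm = (np.linalg.norm(Pt) if norm == "fro"
               else np.linalg.norm(Pt, 2))
        acc = acc + Pt / nrm
    return acc


def diffusion_distance(K: np.ndarray, t_list=DEFAULT_T_LIST,
                       norm: str = "fro") -> DiffusionGeometry:
    """Diffusion distances from the averaged multi-scale diffusion operator.

    P = K / rowsum(K); P_bar = sum_t P^t / ||P^t|| over t in t_list;
    D(i,j) = ||P_bar[i,:] - P_bar[j,:]||_2.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    rs = K.sum(axis=1, keepdims=True)
    if np.any(rs <= 0):
        raise ValueError("K has a nonpositive row sum")
    P = K / rs
    P_bar = _averaged_operator(P, t_list, norm)
    D = squareform(pdist(P_bar))
    Q = distance_distribution(D)
    return DiffusionGeometry(K, P, P_bar, D, Q,
                             params={"t_list": tuple(t_list), "norm": norm})


def distance_distribution(D: np.ndarray) -> np.ndarray:
    """Normalize a distance matrix to a distribution: Q = D / sum_ij D."""
    D = np.asarray(D, dtype=float)
    total = D.sum()
    if total <= 0:
        raise ValueError("all-zero distance matrix: degenerate geometry")
    return D / total


def batch_geometry(batch: OmicsBatch, r: int = 30, k_nn: int = 5,
                   alpha: float = 40.0, t_list=DEFAULT_T_LIST,
                   norm: str = "fro") -> DiffusionGeometry:
    """Full per-batch geometry: reduction -> kernel -> diffusion distances."""
    rep = reduce_dimension(batch, r=min(r, min(batch.counts.shape) - 1))
    K = adaptive_kernel(rep.coords, k_nn=k_nn, alpha=alpha)
    return diffusion_distance(K, t_list=t_list, norm=norm)
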