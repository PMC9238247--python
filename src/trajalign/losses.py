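"""The four loss terms and the per-modality composite objectives.

- distance loss: KL divergence between the normalized pairwise-distance
  distribution of the latent embedding and the normalized diffusion-distance
  distribution of the batch, which forces the embedding to preserve the
  trajectory manifold geometry.
- MMD loss: multi-scale Gaussian-kernel maximum mean discrepancy between two
  batches' embeddings (biased V-statistic), which merges the batches.
- GAM penalty: L1 norm of the gene activity module's end-to-end linear map on
  the region-gene pairs the binary prior marks as non-regulating.
- anchor loss: squared distance between the mean embeddings of anchor cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GeneActivityMatrix
from .nn import GeneActivityNet, Tensor, as_tensor, effective_linear_map

__all__ = [
    "LossWeights",
    "GAMMA_GRID",
    "distance_loss",
    "mmd_loss",
    "gam_penalty",
    "anchor_loss",
    "composite_loss",
    "pairwise_sq_dists",
]

# kernel bandwidth grid {10^u : u = -6..6}
GAMMA_GRID = tuple(10.0 ** u for u in range(-6, 7))

_EPS = 1e-12


@dataclass
class LossWeights:
    lambda_mmd: float = 1.0
    lambda_g: float = 1.0
    anchor_weight: float = 1.0

    def __post_init__(self):
        if min(self.lambda_mmd, self.lambda_g, self.anchor_weight) < 0:
            raise ValueError("loss weights must be nonnegative")


def pairwise_sq_dists(Z1: Tensor, Z2: Tensor) -> Tensor:
    """Squared Euclidean distances between rows of Z1 and rows of Z2."""
    r1 = (Z1 * Z1).sum(axis=1, keepdims=True)
    r2 = (Z2 * Z2).sum(axis=1, keepdims=True)
    return r1 + r2.T - 2.0 * (Z1 @ Z2.T)


def distance_loss(Z, Q_X: np.ndarray) -> Tensor:
    """KL(Q_Z || Q_X) between normalized latent and diffusion distance
    distributions, summed over off-diagonal entries.

    Diagonal entries of both distance matrices are identically zero, so both
    distributions are renormalized over off-diagonal terms and the KL sum is
    taken there; a small epsilon stabilizes the logs.
    """
    Z = as_tensor(Z)
    n = Z.shape[0]
    if n < 3:
        raise ValueError("distance loss needs at least 3 cells")
    Q_X = np.asarray(Q_X, dtype=float)
    if Q_X.shape != (n, n):
        raise ValueError(f"Q_X shape {Q_X.shape} does not match {n} cells")
    dt = Z.data.dtype
    mask = (1.0 - np.eye(n)).astype(dt)
    qx_off = Q_X * mask
    if qx_off.sum() <= 0:
        raise ValueError("Q_X has no off-diagonal mass")
    qx = (qx_off / qx_off.sum()).astype(dt)

    eps = dt.type(_EPS if dt == np.float64 else 1e-8)
    D2 = pairwise_sq_dists(Z, Z)
    D = (D2 * Tensor(mask) + eps) ** 0.5  # eps keeps the sqrt grad finite on the diagonal
    D = D * Tensor(mask)
    Qz = D / D.sum()
    ratio = (Qz + eps) / Tensor(qx + eps)
    return (Qz * ratio.log() * Tensor(mask)).sum()


def mmd_loss(Z1, Z2, gammas=GAMMA_GRID) -> Tensor:
    """Multi-scale Gaussian MMD^2 (biased V-statistic, self-pairs included).

    The three pairwise squared-distance blocks are computed once and reused
    across the bandwidth grid.
    """
    Z1, Z2 = as_tensor(Z1), as_tensor(Z2)
    if Z1.shape[0] == 0 or Z2.shape[0] == 0:
        raise ValueError("MMD needs nonempty point sets")
    if Z1.shape[1] != Z2.shape[1]:
        raise ValueError("embeddings have different dimension")
    # clamp tiny negative values from float cancellation in r1 + r2 - 2 z.z
    D11 = pairwise_sq_dists(Z1, Z1).leaky_relu(0.0)
    D22 = pairwise_sq_dists(Z2, Z2).leaky_relu(0.0)
    D12 = pairwise_sq_dists(Z1, Z2).leaky_relu(0.0)
    return (_multiscale_kernel_mean(D11, gammas)
            + _multiscale_kernel_mean(D22, gammas)
            - 2.0 * _multiscale_kernel_mean(D12, gammas))


def _multiscale_kernel_mean(D2: Tensor, gammas) -> Tensor:
    """sum_gamma mean(exp(-D2 / 2 gamma)) as one fused graph node."""
    coefs = np.asarray([-0.5 / g for g in gammas], dtype=D2.data.dtype)
    exps = [np.exp(c * D2.data) for c in coefs]
    value = sum(float(E.mean()) for E in exps)
    size = D2.data.size

    def backward(g):
        acc = coefs[0] * exps[0]
        for c, E in zip(coefs[1:], exps[1:]):
            acc += c * E
        return (acc * (float(g) / size),)

    out = Tensor(np.asarray(value, dtype=D2.data.dtype))
    if D2.requires_grad:
        out.requires_grad = True
        out._prev = (D2,)
        out._backward = backward
    return out


def gam_penalty(gact: GeneActivityNet, gam: GeneActivityMatrix) -> Tensor:
    """L1 mass of the end-to-end linear map on prior-disallowed pairs.

    Zeros of the prior A are trusted (a 0 means "this region cannot regulate
    this gene"); the penalty is sum |M[r,g]| over those zeros, where M is the
    product of the module's weight matrices.
    """
    M = effective_linear_map(gact)
    A_hat = gam.reversed.astype(M.data.dtype)
    if M.shape != A_hat.shape:
        raise ValueError(
            f"linear map shape {M.shape} does not match GAM shape {A_hat.shape}"
        )
    return (M * Tensor(A_hat)).abs().sum()


def anchor_loss(Z_a, Z_b) -> Tensor:
    """Squared Euclidean distance between the anchor-set mean embeddings."""
    Z_a, Z_b = as_tensor(Z_a), as_tensor(Z_b)
    if Z_a.shape[0] == 0 or Z_b.shape[0] == 0:
        raise ValueError("empty anchor set")
    diff = Z_a.mean(axis=0) - Z_b.mean(axis=0)
    return (diff * diff).sum()


def composite_loss(side: str, Z_self: Tensor, Q_self: np.ndarray,
                   Z_other: Tensor, weights: LossWeights,
                   gact: GeneActivityNet | None = None,
                   gam: GeneActivityMatrix | None = None,
                   anchors_self: Tensor | None = None,
                   anchors_other: Tensor | None = None):
    """Per-modality objective: L_dist + lambda_mmd L_mmd + lambda_g L_GAM
    (+ anchor term). Returns (total, components dict of floats)."""
    if side not in ("RNA", "ATAC"):
        raise ValueError("side must be RNA or ATAC")
    if Q_self is None:
        raise ValueError(f"missing diffusion target Q for the {side} side")
    comps = {}
    total = distance_loss(Z_self, Q_self)
    comps["dist"] = total.item()
    if weights.lambda_mmd > 0:
        lm = mmd_loss(Z_self, Z_other)
        comps["mmd"] = lm.item()
        total = total + weights.lambda_mmd * lm
    else:
        comps["mmd"] = 0.0
    if weights.lambda_g > 0 and gact is not None and gam is not None:
        lg = gam_penalty(gact, gam)
        comps["gam"] = lg.item()
        total = total + weights.lambda_g * lg
    else:
        comps["gam"] = 0.0
    if anchors_self is not None and anchors_other is not None:
        la = anchor_loss(anchors_self, anchors_other)
        comps["anchor"] = la.item()
        total = total + weights.anchor_weight * la
    else:
        comps["anchor"] = 0.0
    comps["total"] = total.item()
    return total, comps
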