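"""Alternating stochastic training of the integration model.

Each epoch interleaves minibatch gradient steps on the two per-modality
objectives: an ATAC step feeds accessibility through the gene activity module
and the projection module and updates both; an RNA step feeds expression
through the projection module only and updates only the projection module
(the gene activity module runs in eval mode and is left bitwise untouched).
The diffusion-distance targets are precomputed per batch once; a minibatch's
target distribution is the corresponding submatrix, renormalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .diffusion import DiffusionGeometry, batch_geometry
from .io import GeneActivityMatrix, OmicsBatch
from .losses import (GAMMA_GRID, LossWeights, anchor_loss, composite_loss,
                     mmd_loss)
from .nn import Adam, ModelState, Tensor, gene_activity_forward, init_model, project

__all__ = [
    "TrainConfig",
    "IntegrationResult",
    "train_integration",
    "quantile_normalize_distances",
    "multi_batch_mmd",
]


@dataclass
class TrainConfig:
    epochs: int = 500
    learning_rate: float = 5e-4
    minibatch_size: int = 512
    latent_dim: int = 8
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    use_anchor: bool = False
    anchors_rna: list[np.ndarray] | None = None   # per RNA batch, row indices
    anchors_atac: list[np.ndarray] | None = None  # per ATAC batch, row indices
    hidden_gact: tuple = (1024, 512)
    hidden_proj: tuple = (512, 128)
    reduce_r: int = 30
    k_nn: int = 5
    alpha: float = 40.0
    t_list: tuple = (30, 50, 70)
    use_norm: bool = True
    warm_start: bool = True  # start the gene activity module at the prior
    quantile_norm: bool | None = None  # None: only with >2 batches
    dtype: type = np.float32  # training precision; analytic checks use float64

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.minibatch_size < 3:
            raise ValueError("minibatch_size must be >= 3 (distance loss)")


@dataclass
class IntegrationResult:
    Z_rna: list[np.ndarray]
    Z_atac: list[np.ndarray]
    model: ModelState
    pseudo_rna: list[np.ndarray]  # one cells x genes matrix per ATAC batch
    trace: list[dict]             # per-epoch loss components
    geometries: dict = field(default_factory=dict)

    @property
    def Z_joint(self) -> np.ndarray:
        return np.vstack(self.Z_rna + self.Z_atac)


def quantile_normalize_distances(D_ref: np.ndarray, D_target: np.ndarray,
                                 seed: int = 0) -> np.ndarray:
    """Map D_target onto the value distribution of D_ref, rank for rank.

    Values are sampled from D_ref with replacement to fill a matrix the size
    of D_target; both are sorted and each entry of D_target is replaced by
    the equally ranked sampled value. Rank order of D_target is preserved.
    """
    D_ref = np.asarray(D_ref, dtype=float)
    D_target = np.asarray(D_target, dtype=float)
    if D_ref.size == 0 or D_target.size == 0:
        raise ValueError("empty distance matrix")
    rng = np.random.default_rng(seed)
    sampled = np.sort(rng.choice(D_ref.ravel(), size=D_target.size, replace=True))
    order = np.argsort(D_target.ravel(), kind="stable")
    out = np.empty(D_target.size)
    out[order] = sampled
    return out.reshape(D_target.shape)


def multi_batch_mmd(Z_list: list, ref_index: int = 0,
                    gammas=GAMMA_GRID) -> Tensor:
    """Sum of MMD losses between every non-reference batch and the reference."""
    if not 0 <= ref_index < len(Z_list):
        raise ValueError("ref_index out of range")
    if len(Z_list) == 1:
        warnings.warn("single batch: multi-batch MMD is 0")
        return Tensor(0.0)
    total = None
    for i, Z in enumerate(Z_list):
        if i == ref_index:
            continue
        term = mmd_loss(Z, Z_list[ref_index], gammas)
        total = term if total is None else total + term
    return total


def _minibatch_q(D: np.ndarray, idx: np.ndarray) -> np.ndarray:
    sub = D[np.ix_(idx, idx)]
    tot = sub.sum()
    if tot <= 0:
        tot = 1.0
    return sub / tot


def _rna_tensor(batch: OmicsBatch) -> np.ndarray:
    return batch.dense()


def train_integration(rna_batches: list[OmicsBatch],
                      atac_batches: list[OmicsBatch],
                      gam: GeneActivityMatrix, config: TrainConfig,
                      geometries: dict | None = None,
                      verbose: bool = False) -> IntegrationResult:
    """Train the gene activity + projection modules on preprocessed batches.

    rna_batches carry log-normalized expression over the GAM's gene set;
    atac_batches carry binary accessibility over the GAM's region set.
    Returns eval-mode embeddings per batch, pseudo gene expression for every
    ATAC batch, and the per-epoch loss trace. With more than two batches in
    total, each batch's diffusion distance matrix is quantile normalized
    against the reference (first RNA) batch's before training.
    """
    if not rna_batches or not atac_batches:
        raise ValueError("need at least one batch per modality")
    n_genes = len(gam.gene_ids)
    n_regions = len(gam.region_ids)
    for b in rna_batches:
        if b.n_features != n_genes:
            raise ValueError("RNA batch feature count does not match GAM genes")
    for b in atac_batches:
        if b.n_features != n_regions:
            raise ValueError("ATAC batch feature count does not match GAM regions")

    rng = np.random.default_rng(config.seed)
    warm = (config.warm_start
            and n_genes <= min(config.hidden_gact))
    model = init_model(n_regions, n_genes, config.latent_dim, seed=config.seed,
                       hidden_gact=config.hidden_gact,
                       hidden_proj=config.hidden_proj,
                       use_norm=config.use_norm,
                       gam_init=gam.A if warm else None, dtype=config.dtype)

    # ----- diffusion geometry targets (precomputed once per batch) --------
    geoms: dict[tuple, DiffusionGeometry] = dict(geometries or {})
    for kind, batches in (("RNA", rna_batches), ("ATAC", atac_batches)):
        for i, b in enumerate(batches):
            if (kind, i) not in geoms:
                geoms[(kind, i)] = batch_geometry(
                    b, r=config.reduce_r, k_nn=config.k_nn,
                    alpha=config.alpha, t_list=config.t_list)
    D = {k: g.D.copy() for k, g in geoms.items()}
    n_total_batches = len(rna_batches) + len(atac_batches)
    do_qn = (config.quantile_norm if config.quantile_norm is not None
             else n_total_batches > 2)
    if do_qn:
        ref = D[("RNA", 0)]
        for k in D:
            if k != ("RNA", 0):
                D[k] = quantile_normalize_distances(ref, D[k], seed=config.seed)

    X_rna = [_rna_tensor(b).astype(config.dtype) for b in rna_batches]
    X_atac = [b.dense().astype(config.dtype) for b in atac_batches]
    anchors_rna = config.anchors_rna if config.use_anchor else None
    anchors_atac = config.anchors_atac if config.use_anchor else None

    opt_all = Adam(model.parameters(), lr=config.learning_rate)
    opt_proj = Adam(model.proj.parameters(), lr=config.learning_rate)

    def embed_joint(parts):
        """Project several gene-space minibatches in one forward pass.

        Concatenating the parts makes the projection module's normalization
        statistics shared across modalities, so a distribution gap between
        expression and pseudo-expression survives to the latent space where
        the MMD term can close it (per-part statistics would silently absorb
        the gap during training and reintroduce it at inference).
        """
        rows = [p.shape[0] for p in parts]
        if len(parts) == 1:
            stacked = parts[0]
        else:
            datas = [p.data if isinstance(p, Tensor) else p for p in parts]
            joined = Tensor(np.vstack(datas))
            if any(isinstance(p, Tensor) and p.requires_grad for p in parts):
                joined.requires_grad = True
                tensor_parts = [p for p in parts if isinstance(p, Tensor)]
                offsets = np.cumsum([0] + rows)

                def backward(g):
                    return tuple(
                        g[offsets[i]:offsets[i + 1]]
                        for i, p in enumerate(parts)
                        if isinstance(p, Tensor))
                joined._prev = tuple(tensor_parts)
                joined._backward = backward
            stacked = joined
        Z = project(model.proj, stacked)
        out, at = [], 0
        for r in rows:
            out.append(Z[at:at + r])
            at += r
        return out

    def pseudo_expression(i, idx):
        return gene_activity_forward(model.gact, X_atac[i][idx])

    def sample(n):
        m = min(config.minibatch_size, n)
        return rng.choice(n, size=m, replace=False)

    trace: list[dict] = []
    steps = [("ATAC", i) for i in range(len(atac_batches))] + \
            [("RNA", i) for i in range(len(rna_batches))]
    # interleave: ATAC step, RNA step, ATAC step, ...
    order = []
    a = [s for s in steps if s[0] == "ATAC"]
    r_ = [s for s in steps if s[0] == "RNA"]
    for i in range(max(len(a), len(r_))):
        if i < len(a):
            order.append(a[i])
        if i < len(r_):
            order.append(r_[i])

    n_inner = max(int(np.ceil(max(b.n_cells for b in rna_batches + atac_batches)
                              / config.minibatch_size)), 1)

    for epoch in range(config.epochs):
        comps_sum: dict[str, float] = {}
        n_steps = 0
        for _ in range(n_inner):
            for kind, i in order:
                if kind == "ATAC":
                    model.train(True)
                    idx = sample(atac_batches[i].n_cells)
                    jdx = sample(rna_batches[0].n_cells)
                    parts = [pseudo_expression(i, idx), X_rna[0][jdx]]
                    if anchors_atac is not None and anchors_rna is not None:
                        parts += [pseudo_expression(
                            i, np.asarray(anchors_atac[i])),
                            X_rna[0][np.asarray(anchors_rna[0])]]
                    Zs = embed_joint(parts)
                    Z_self, Z_other = Zs[0], Zs[1]
                    anc_s, anc_o = (Zs[2], Zs[3]) if len(Zs) > 2 else (None,
                                                                       None)
                    total, comps = composite_loss(
                        "ATAC", Z_self, _minibatch_q(D[("ATAC", i)], idx),
                        Z_other, config.weights, gact=model.gact, gam=gam,
                        anchors_self=anc_s, anchors_other=anc_o)
                    if not np.isfinite(total.item()):
                        bad = max(comps, key=lambda k: abs(comps[k]))
                        raise FloatingPointError(
                            f"non-finite ATAC-side loss at epoch {epoch} "
                            f"(worst term: {bad})")
                    opt_all.zero_grad()
                    total.backward()
                    opt_all.step()
                else:
                    # RNA step: gene activity module frozen (eval mode, no update)
                    model.proj.train(True)
                    model.gact.train(False)
                    idx = sample(rna_batches[i].n_cells)
                    jdx = sample(atac_batches[0].n_cells)
                    parts = [X_rna[i][idx], pseudo_expression(0, jdx)]
                    if anchors_rna is not None and anchors_atac is not None:
                        parts += [X_rna[i][np.asarray(anchors_rna[i])],
                                  pseudo_expression(
                                      0, np.asarray(anchors_atac[0]))]
                    Zs = embed_joint(parts)
                    Z_self, Z_other = Zs[0], Zs[1]
                    anc_s, anc_o = (Zs[2], Zs[3]) if len(Zs) > 2 else (None,
                                                                       None)
                    total, comps = composite_loss(
                        "RNA", Z_self, _minibatch_q(D[("RNA", i)], idx),
                        Z_other, config.weights, gact=model.gact, gam=gam,
                        anchors_self=anc_s, anchors_other=anc_o)
                    if not np.isfinite(total.item()):
                        bad = max(comps, key=lambda k: abs(comps[k]))
                        raise FloatingPointError(
                            f"non-finite RNA-side loss at epoch {epoch} "
                            f"(worst term: {bad})")
                    opt_proj.zero_grad()
                    for p in model.gact.parameters():
                        p.grad = None
                    total.backward()
                    opt_proj.step()
                for k, v in comps.items():
                    comps_sum[k] = comps_sum.get(k, 0.0) + v
                n_steps += 1
        rec = {"epoch": epoch,
               **{k: v / n_steps for k, v in comps_sum.items()}}
        trace.append(rec)
        if verbose and (epoch % 50 == 0 or epoch == config.epochs - 1):
            print(f"epoch {epoch}: " +
                  ", ".join(f"{k}={v:.4f}" for k, v in rec.items()
                            if k != "epoch"))

    # ----- full-batch inference: one shared projection forward ------------
    model.inference_mode()
    pseudo = [gene_activity_forward(model.gact, X).data for X in X_atac]
    Zs = embed_joint([*X_rna, *(Tensor(p) for p in pseudo)])
    Z_rna = [z.data for z in Zs[:len(X_rna)]]
    Z_atac = [z.data for z in Zs[len(X_rna):]]
    return IntegrationResult(Z_rna, Z_atac, model, pseudo, trace,
                             geometries=geoms)
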