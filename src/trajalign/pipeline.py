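"""End-to-end workflows tying the pieces together.

`prepare_batches` applies the standard preprocessing (library-size
log-normalization for RNA, binarization + GAM-linked region filtering for
ATAC; feature filtering is skipped for simulated data). `integrate` trains
the model and optionally applies MNN smoothing. `simulated_run` is the whole
loop on one simulated dataset and returns everything the evaluation metrics
need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GeneActivityMatrix, OmicsBatch, preprocess_atac, preprocess_rna
from .postprocess import refine_all_pairs
from .sim import (SimulationTruth, add_noise_and_split, assign_batches,
                  preset_tree, simulate_joint)
from .train import IntegrationResult, TrainConfig, train_integration
from .trajectory import infer_trajectory

__all__ = ["prepare_batches", "integrate", "SimulatedRun", "simulated_run"]


def prepare_batches(rna_batches: list[OmicsBatch],
                    atac_batches: list[OmicsBatch],
                    gam: GeneActivityMatrix,
                    n_hvg: int | None = None):
    """Standard preprocessing for both modalities against a shared GAM.

    n_hvg=None (simulated data) keeps all genes. The GAM is subset once by
    the first ATAC batch's region filter and reused for the rest, so every
    batch ends aligned to the same feature sets.
    """
    rna_out = [preprocess_rna(b, n_hvg=n_hvg) for b in rna_batches]
    genes = rna_out[0].feature_ids
    gidx = [gam.gene_ids.index(g) for g in genes]
    gam_g = GeneActivityMatrix(gam.A[:, gidx], list(gam.region_ids), list(genes))
    atac_out = []
    gam_sub = None
    for b in atac_batches:
        bb, gam_b = preprocess_atac(b, gam_g if gam_sub is None else gam_sub)
        gam_sub = gam_b
        atac_out.append(bb)
    return rna_out, atac_out, gam_sub


def integrate(rna_batches, atac_batches, gam, config: TrainConfig,
              postprocess: bool = True, verbose: bool = False
              ) -> IntegrationResult:
    """Train and (optionally) MNN-smooth; returns the integration result with
    refined embeddings substituted in when postprocess is on."""
    res = train_integration(rna_batches, atac_batches, gam, config,
                            verbose=verbose)
    if postprocess:
        refined = refine_all_pairs(res.Z_rna + res.Z_atac)
        res.Z_rna = refined[:len(res.Z_rna)]
        res.Z_atac = refined[len(res.Z_rna):]
    return res


@dataclass
class SimulatedRun:
    truth: SimulationTruth
    batches_rna: list[OmicsBatch]
    batches_atac: list[OmicsBatch]
    result: IntegrationResult
    cell_order: np.ndarray        # truth row index per joint-embedding row
    pseudotime: np.ndarray | None = None
    branches: np.ndarray | None = None
    f1_inputs: tuple | None = None


def simulated_run(preset: str = "trifurcating", cells_per_batch: int = 1500,
                  n_genes: int = 100, n_regions: int = 400,
                  capture_eff: float = 0.25, batch_effect_sd: float = 0.2,
                  config: TrainConfig | None = None, seed: int = 0,
                  run_trajectory: bool = True,
                  batch_sizes: list[int] | None = None,
                  postprocess: bool = True) -> SimulatedRun:
    """Simulate one unmatched two-batch dataset, integrate it, and infer the
    joint trajectory rooted at the true earliest cell."""
    tree = preset_tree(preset, cells_per_batch=cells_per_batch)
    truth = simulate_joint(tree, n_genes=n_genes, n_regions=n_regions,
                           seed=seed, cluster_mode=(preset == "clusters"))
    assign_batches(truth, n_batches=2, seed=seed + 1, sizes=batch_sizes)
    raw = add_noise_and_split(
        truth, capture_eff=[capture_eff, capture_eff],
        batch_effect_sd=batch_effect_sd,
        keep={"rna_batch_indices": [0], "atac_batch_indices": [1]},
        seed=seed + 2)
    rna_raw = [b for b in raw if b.modality == "RNA"]
    atac_raw = [b for b in raw if b.modality == "ATAC"]
    rna, atac, gam = prepare_batches(rna_raw, atac_raw, truth.true_gam,
                                     n_hvg=None)
    config = config or TrainConfig()
    res = integrate(rna, atac, gam, config, postprocess=postprocess)

    order = np.concatenate([np.flatnonzero(truth.batch_of == 0),
                            np.flatnonzero(truth.batch_of == 1)])
    run = SimulatedRun(truth, rna, atac, res, order)
    if run_trajectory:
        Z = res.Z_joint
        true_t = truth.pseudotime[order]
        root = int(np.argmin(true_t))
        traj = infer_trajectory(Z, root=root, seed=config.seed)
        run.pseudotime = traj.pseudotime
        run.branches = traj.branch_labels
        run.f1_inputs = (truth.branch[order], traj.branch_labels)
    return run
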