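"""Count-matrix and annotation I/O, gene-activity-matrix construction, preprocessing.

The gene activity matrix (GAM) is the binary regions x genes prior that marks
which accessible regions may regulate which genes, built purely from genomic
proximity: a region is linked to a gene when it overlaps the window 2000 bp
upstream of the gene body (strand-aware) and, optionally, the gene body itself.

Internal coordinates are 0-based half-open throughout; GTF input (1-based,
closed) is converted on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "GenomicInterval",
    "OmicsBatch",
    "GeneActivityMatrix",
    "load_count_matrix",
    "save_count_matrix",
    "read_bed",
    "read_gtf",
    "construct_gam",
    "preprocess_rna",
    "preprocess_atac",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval; strand is required for genes."""

    chrom: str
    start: int
    end: int
    strand: str | None = None
    name: str | None = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(
                f"interval {self.name or ''} has start {self.start} >= end {self.end}"
            )
        if self.strand is not None and self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class OmicsBatch:
    """One modality's cells x features count matrix with identifiers.

    counts may be dense ndarray or scipy sparse; it is never negative.
    feature_coords, when present, carries one GenomicInterval per feature.
    """

    counts: np.ndarray | sp.spmatrix
    modality: str  # "RNA" or "ATAC"
    cell_ids: list[str]
    feature_ids: list[str]
    batch_id: str = "batch0"
    feature_coords: list[GenomicInterval] | None = None

    def __post_init__(self):
        if self.modality not in ("RNA", "ATAC"):
            raise ValueError(f"modality must be RNA or ATAC, got {self.modality!r}")
        n, m = self.counts.shape
        if n != len(self.cell_ids):
            raise ValueError(
                f"counts has {n} rows but {len(self.cell_ids)} cell ids"
            )
        if m != len(self.feature_ids):
            raise ValueError(
                f"counts has {m} columns but {len(self.feature_ids)} feature ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature_ids")
        if self.feature_coords is not None and len(self.feature_coords) != m:
            raise ValueError("feature_coords must have one entry per feature")
        mn = self.counts.min() if sp.issparse(self.counts) else np.min(self.counts)
        if mn < 0:
            raise ValueError("counts has negative entries")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        X = self.counts
        return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)


@dataclass
class GeneActivityMatrix:
    """Binary regions x genes prior A and its elementwise reversal 1 - A."""

    A: np.ndarray
    region_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self):
        self.A = np.asarray(self.A)
        if self.A.shape != (len(self.region_ids), len(self.gene_ids)):
            raise ValueError("GAM shape does not match region/gene id counts")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("GAM entries must be binary")
        self.A = self.A.astype(float)

    @property
    def reversed(self) -> np.ndarray:
        """1 - A: marks region-gene pairs believed to carry no regulation."""
        return 1.0 - self.A


# ---------------------------------------------------------------------------
# count-matrix readers / writers
# ---------------------------------------------------------------------------

def load_count_matrix(path, fmt: str, modality: str = "RNA",
                      batch_id: str = "batch0") -> OmicsBatch:
    """Load a cells x features matrix from an MTX directory, CSV or H5AD file.

    mtx_dir expects matrix.mtx (features x cells, CellRanger orientation is
    auto-detected from the barcode/feature counts), barcodes.tsv, features.tsv.
    CSV expects a header row of feature names and a first column of cell ids.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        return OmicsBatch(df.to_numpy(dtype=float), modality,
                          [str(i) for i in df.index], [str(c) for c in df.columns],
                          batch_id)
    if fmt == "mtx_dir":
        M = mmread(os.path.join(path, "matrix.mtx")).tocsr()
        barcodes = pd.read_csv(os.path.join(path, "barcodes.tsv"),
                               header=None, sep="\t")[0].astype(str).tolist()
        feats = pd.read_csv(os.path.join(path, "features.tsv"),
                            header=None, sep="\t")[0].astype(str).tolist()
        if M.shape == (len(feats), len(barcodes)):
            M = M.T.tocsr()
        elif M.shape != (len(barcodes), len(feats)):
            raise ValueError(
                f"matrix shape {M.shape} matches neither (cells, features)="
                f"({len(barcodes)}, {len(feats)}) nor its transpose"
            )
        return OmicsBatch(M, modality, barcodes, feats, batch_id)
    if fmt == "h5ad":
        import anndata as ad

        A = ad.read_h5ad(path)
        return OmicsBatch(A.X if sp.issparse(A.X) else np.asarray(A.X),
                          modality, A.obs_names.astype(str).tolist(),
                          A.var_names.astype(str).tolist(), batch_id)
    raise ValueError(f"unknown format {fmt!r}")


def save_count_matrix(batch: OmicsBatch, path) -> None:
    """Write an OmicsBatch as an MTX directory (matrix.mtx cells x features)."""
    os.makedirs(path, exist_ok=True)
    M = batch.counts if sp.issparse(batch.counts) else sp.csr_matrix(batch.counts)
    mmwrite(os.path.join(path, "matrix.mtx"), M)
    pd.Series(batch.cell_ids).to_csv(os.path.join(path, "barcodes.tsv"),
                                     index=False, header=False)
    pd.Series(batch.feature_ids).to_csv(os.path.join(path, "features.tsv"),
                                        index=False, header=False)


def read_bed(path) -> list[GenomicInterval]:
    """Read regions from BED (already 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for _, row in df.iterrows():
        name = str(row[3]) if df.shape[1] > 3 else f"{row[0]}:{row[1]}-{row[2]}"
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), name=name))
    return out


def read_gtf(path, feature: str = "gene") -> list[GenomicInterval]:
    """Read gene intervals from GTF/GFF; converts 1-based closed to 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "source", "feature", "start", "end",
                            "score", "strand", "frame", "attr"])
    df = df[df["feature"] == feature]
    out = []
    for _, row in df.iterrows():
        attr = str(row["attr"])
        name = None
        for key in ("gene_id", "ID", "gene_name"):
            if key in attr:
                frag = attr.split(key, 1)[1]
                name = frag.split(";")[0].strip(' "=')
                break
        out.append(GenomicInterval(str(row["chrom"]), int(row["start"]) - 1,
                                   int(row["end"]), str(row["strand"]), name))
    return out


# ---------------------------------------------------------------------------
# GAM construction
# ---------------------------------------------------------------------------

def _regulatory_window(gene: GenomicInterval, upstream: int,
                       include_gene_body: bool) -> tuple[int, int]:
    if gene.strand == "+":
        lo, hi = gene.start - upstream, gene.start
        if include_gene_body:
            hi = gene.end
    else:
        lo, hi = gene.end, gene.end + upstream
        if include_gene_body:
            lo = gene.start
    return max(lo, 0), hi


def construct_gam(regions: list[GenomicInterval], genes: list[GenomicInterval],
                  upstream_window: int = 2000,
                  include_gene_body: bool = True) -> GeneActivityMatrix:
    """Build the binary regions x genes prior from genomic proximity.

    A[r, g] = 1 iff region r overlaps the 2000 bp (default) window upstream of
    gene g's body on the gene's strand, or (with include_gene_body, the
    default) the gene body itself. Regions on chromosomes without genes get
    all-zero rows.
    """
    for g in genes:
        if g.strand is None:
            raise ValueError(f"gene {g.name or g} has no strand")
    A = np.zeros((len(regions), len(genes)))
    windows = [_regulatory_window(g, upstream_window, include_gene_body)
               for g in genes]
    by_chrom: dict[str, list[int]] = {}
    for j, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append(j)
    for i, r in enumerate(regions):
        for j in by_chrom.get(r.chrom, ()):
            lo, hi = windows[j]
            if r.start < hi and lo < r.end:
                A[i, j] = 1.0
    region_ids = [r.name or f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    gene_ids = [g.name or f"gene{j}" for j, g in enumerate(genes)]
    return GeneActivityMatrix(A, region_ids, gene_ids)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_rna(batch: OmicsBatch, n_hvg: int | None = None) -> OmicsBatch:
    """Library-size normalize, log-transform, and keep the n_hvg most variable genes.

    Each cell is scaled so its library size equals the batch median library
    size, then log(1 + x) is applied. Highly variable genes are ranked by
    dispersion (variance / mean of the log-normalized values), ties broken by
    feature id. n_hvg=None skips gene filtering (the simulated-data path).
    """
    if batch.modality != "RNA":
        raise ValueError("preprocess_rna expects an RNA batch")
    X = batch.dense()
    lib = X.sum(axis=1)
    if np.any(lib == 0):
        bad = batch.cell_ids[int(np.argmin(lib))]
        raise ValueError(f"cell {bad!r} has zero library size")
    c = float(np.median(lib))
    L = np.log1p(X * (c / lib)[:, None])
    if n_hvg is None or n_hvg >= batch.n_features:
        keep = np.arange(batch.n_features)
    else:
        mean = L.mean(axis=0)
        var = L.var(axis=0)
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
        order = sorted(range(batch.n_features),
                       key=lambda j: (-disp[j], batch.feature_ids[j]))
        keep = np.sort(np.array(order[:n_hvg]))
    coords = ([batch.feature_coords[j] for j in keep]
              if batch.feature_coords is not None else None)
    return replace(batch, counts=L[:, keep],
                   feature_ids=[batch.feature_ids[j] for j in keep],
                   feature_coords=coords)


def preprocess_atac(batch: OmicsBatch,
                    gam: GeneActivityMatrix) -> tuple[OmicsBatch, GeneActivityMatrix]:
    """Binarize accessibility and keep only regions linked to at least one gene.

    The GAM is subset to the same rows so its region order matches the
    returned batch's feature order exactly.
    """
    if batch.modality != "ATAC":
        raise ValueError("preprocess_atac expects an ATAC batch")
    missing = set(gam.region_ids) - set(batch.feature_ids)
    if missing:
        raise ValueError(f"GAM regions not in batch: {sorted(missing)[:5]}")
    X = (batch.dense() > 0).astype(float)
    col = {f: j for j, f in enumerate(batch.feature_ids)}
    order = [col[r] for r in gam.region_ids]
    X = X[:, order]
    keep = np.flatnonzero(gam.A.sum(axis=1) > 0)
    if keep.size == 0:
        raise ValueError(
            "no region is linked to any gene; widen the upstream window"
        )
    region_ids = [gam.region_ids[i] for i in keep]
    coords = ([batch.feature_coords[col[r]] for r in region_ids]
              if batch.feature_coords is not None else None)
    out = replace(batch, counts=X[:, keep], feature_ids=region_ids,
                  feature_coords=coords)
    sub = GeneActivityMatrix(gam.A[keep], region_ids, list(gam.gene_ids))
    return out, sub
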