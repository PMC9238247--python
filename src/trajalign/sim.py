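"""Joint scRNA + scATAC simulation along a branching trajectory.

Cells evolve along a user-given rooted tree through a Brownian motion of a
low-dimensional "chromatin identity" vector. Region accessibility is the
product of cell and region identity vectors, rank-mapped onto a sparse
binary target distribution (region-wise Bernoulli rates drawn from a Beta:
a built-in parametric stand-in for an empirical reference accessibility
profile; pass `reference_distribution` to use a real one). Expression then
follows the two-state promoter kinetic model: a gene toggles on at rate
k_on and off at rate k_off, synthesizes at rate s while on, transcripts
degrade at rate d; the stationary law is Beta-Poisson
(p ~ Beta(k_on/d, k_off/d), x ~ Poisson(p s / d)). Accessibility feeds back
on transcription by scaling k_on with the fraction of a gene's GAM-linked
regions that are open in that cell, which couples the two modalities
through a known ground-truth GAM.

Technical noise (binomial capture), gene-wise multiplicative batch effects
and a single-modality split produce the unmatched batches a diagonal
integration method sees, while the matched truth is retained for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GeneActivityMatrix, OmicsBatch

__all__ = [
    "TrajectoryTree",
    "KineticParams",
    "SimulationTruth",
    "simulate_identities",
    "simulate_atac",
    "simulate_rna",
    "add_noise_and_split",
    "simulate_joint",
    "preset_tree",
    "random_gam",
]


@dataclass
class TrajectoryTree:
    """Rooted tree: edges (parent, child, length, n_cells)."""

    edges: list[tuple[str, str, float, int]]
    root: str

    def __post_init__(self):
        if not self.edges:
            raise ValueError("empty tree")
        children = {c for _, c, _, _ in self.edges}
        parents = {p for p, _, _, _ in self.edges}
        if self.root in children:
            raise ValueError("root cannot be a child")
        dangling = (parents - children) - {self.root}
        if dangling:
            raise ValueError(f"parents not reachable from root: {dangling}")
        if any(n < 0 or l < 0 for _, _, l, n in self.edges):
            raise ValueError("negative edge length or cell allocation")

    @property
    def n_cells(self) -> int:
        return sum(n for _, _, _, n in self.edges)

    def depths(self) -> dict[str, float]:
        d = {self.root: 0.0}
        rest = list(self.edges)
        while rest:
            again = []
            for p, c, l, _ in rest:
                if p in d:
                    d[c] = d[p] + l
                else:
                    again.append((p, c, l, 0))
            if len(again) == len(rest):
                raise ValueError("tree is not connected")
            rest = again
        return d


@dataclass
class KineticParams:
    """Two-state promoter rates; k_on is cells x genes, the rest per gene."""

    k_on: np.ndarray
    k_off: np.ndarray
    s: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        for name in ("k_on", "k_off", "s", "d"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulationTruth:
    rna_counts: np.ndarray       # N x G, matched row order with atac_counts
    atac_counts: np.ndarray      # N x R, binary
    true_gam: GeneActivityMatrix
    pseudotime: np.ndarray
    branch: np.ndarray           # branch (edge) label per cell
    cell_identities: np.ndarray  # N x v
    region_identities: np.ndarray  # R x v
    kinetics: KineticParams | None = None
    batch_of: np.ndarray | None = None


# ---------------------------------------------------------------------------
# identities along the tree
# ---------------------------------------------------------------------------

def simulate_identities(tree: TrajectoryTree, v: int = 20,
                        step_sd: float = 1.0, seed: int = 0
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Brownian evolution of cell identity vectors along the tree.

    Node identities follow child = parent + N(0, step_sd^2 * length) per
    coordinate. A cell at fraction u of an edge interpolates the two node
    identities and adds an independent Brownian-bridge increment with
    variance step_sd^2 * u(1-u) * length, so the squared displacement from
    the root grows linearly in pseudotime. Returns (identities, pseudotime,
    branch labels); a cell's branch label is its edge's "parent_child" name.
    """
    if v < 1:
        raise ValueError("identity dimension v must be >= 1")
    if step_sd <= 0:
        raise ValueError("step_sd must be positive")
    rng = np.random.default_rng(seed)
    node_id = {tree.root: rng.normal(0.0, 1.0, size=v)}
    depths = tree.depths()
    # resolve edges root-outward
    rest = list(tree.edges)
    ordered = []
    while rest:
        again = []
        for e in rest:
            (ordered if e[0] in node_id or e[0] == tree.root else again).append(e)
            if e[0] in node_id and e[1] not in node_id:
                p, c, l, _ = e
                node_id[c] = node_id[p] + rng.normal(0.0, step_sd * np.sqrt(l), v)
        rest = again

    ids, times, branches = [], [], []
    for p, c, l, n in ordered:
        if n == 0:
            continue
        u = rng.uniform(0.0, 1.0, size=n)
        u.sort()
        interp = node_id[p][None, :] + u[:, None] * (node_id[c] - node_id[p])[None, :]
        bridge_sd = step_sd * np.sqrt(np.maximum(u * (1 - u) * l, 0.0))
        ids.append(interp + rng.normal(size=(n, v)) * bridge_sd[:, None])
        times.append(depths[p] + u * l)
        branches.extend([f"{p}_{c}"] * n)
    return np.vstack(ids), np.concatenate(times), np.asarray(branches)


# ---------------------------------------------------------------------------
# accessibility
# ---------------------------------------------------------------------------

def simulate_atac(cell_identities: np.ndarray, n_regions: int,
                  noise: float = 0.1, seed: int = 0,
                  reference_distribution: np.ndarray | None = None,
                  beta_params: tuple[float, float] = (1.0, 8.0)
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Binary accessibility by rank-mapping identity products onto a sparse
    target distribution.

    The non-realistic matrix is cell_identities @ region_identities.T plus
    Gaussian noise. Per region, a target number of open cells is drawn
    (Bernoulli rate ~ Beta(a, b), default mean 1/9 for scATAC-like sparsity,
    or the empirical rate of the same-index column of
    reference_distribution), and the cells with the highest non-realistic
    values are set open — a monotone, rank-preserving map.
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(cell_identities, float)
    n, v = ids.shape
    region_ids = rng.normal(0.0, 1.0, size=(n_regions, v)) / np.sqrt(v)
    raw = ids @ region_ids.T
    if noise > 0:
        raw = raw + rng.normal(0.0, noise * raw.std(), size=raw.shape)
    if reference_distribution is not None:
        ref = np.asarray(reference_distribution) > 0
        rates = ref.mean(axis=0)
        rates = rates[rng.integers(0, rates.size, size=n_regions)]
    else:
        rates = rng.beta(*beta_params, size=n_regions)
    X = np.zeros((n, n_regions))
    m_open = rng.binomial(n, rates)
    for j in range(n_regions):
        if m_open[j] == 0:
            continue
        top = np.argsort(raw[:, j], kind="stable")[-m_open[j]:]
        X[top, j] = 1.0
    return X, region_ids


def random_gam(n_regions: int, n_genes: int, links_per_gene: int = 3,
               seed: int = 0) -> GeneActivityMatrix:
    """Random binary ground-truth GAM with a fixed number of regions wired
    to each gene."""
    rng = np.random.default_rng(seed)
    A = np.zeros((n_regions, n_genes))
    for g in range(n_genes):
        rows = rng.choice(n_regions, size=min(links_per_gene, n_regions),
                          replace=False)
        A[rows, g] = 1.0
    return GeneActivityMatrix(A, [f"region{i}" for i in range(n_regions)],
                              [f"gene{j}" for j in range(n_genes)])


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def base_kinetics(cell_identities: np.ndarray, n_genes: int, seed: int = 0
                  ) -> KineticParams:
    """Kinetic rates: k_off, s, d log-normal per gene; base k_on per
    cell-gene via a softplus of identity-effect dot products, so the burst
    frequency varies smoothly along the trajectory."""
    rng = np.random.default_rng(seed)
    ids = np.asarray(cell_identities, float)
    n, v = ids.shape
    effect = rng.normal(0.0, 1.0, size=(v, n_genes)) / np.sqrt(v)
    act = ids @ effect
    k_on = np.log1p(np.exp(act))  # softplus, strictly positive
    k_off = rng.lognormal(np.log(1.5), 0.3, size=n_genes)
    s = rng.lognormal(np.log(50.0), 0.4, size=n_genes)
    d = rng.lognormal(0.0, 0.2, size=n_genes)
    return KineticParams(k_on, k_off, s, d)


def simulate_rna(atac_counts: np.ndarray, true_gam: GeneActivityMatrix,
                 kinetics: KineticParams, seed: int = 0,
                 coupling: tuple[float, float] = (0.5, 1.5)) -> np.ndarray:
    """Beta-Poisson transcript counts with accessibility-scaled k_on.

    Per cell and gene, k_on is multiplied by a monotone bounded function of
    the fraction of the gene's GAM-linked regions open in the cell,
    g(f) = c0 + c1 * f (default 0.5 + 1.5 f), then counts are drawn from the
    two-state model's stationary law.
    """
    rng = np.random.default_rng(seed)
    X_atac = np.asarray(atac_counts, float) > 0
    A = true_gam.A
    if A.shape[0] != X_atac.shape[1]:
        raise ValueError("GAM rows must match ATAC regions")
    links = A.sum(axis=0)  # regions per gene
    open_counts = X_atac @ A
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(links > 0, open_counts / np.maximum(links, 1), 0.0)
    c0, c1 = coupling
    scale = np.where(links > 0, c0 + c1 * frac, 1.0)
    if np.any(links == 0):
        import warnings

        warnings.warn(f"{int((links == 0).sum())} genes have no GAM-linked "
                      "regions; base k_on used")
    k_on = kinetics.k_on * scale
    a = k_on / kinetics.d
    b = kinetics.k_off / kinetics.d
    p = rng.beta(np.maximum(a, 1e-6), np.maximum(b, 1e-6))
    lam = p * (kinetics.s / kinetics.d)
    return rng.poisson(lam).astype(float)


# ---------------------------------------------------------------------------
# noise, batch effects, single-modality split
# ---------------------------------------------------------------------------

def add_noise_and_split(truth: SimulationTruth, capture_eff: list[float],
                        batch_effect_sd: float,
                        keep: dict, seed: int = 0,
                        atac_flip: float = 0.0) -> list[OmicsBatch]:
    """Binomial capture noise + gene-wise batch factors, then keep one
    modality per batch.

    keep = {"rna_batch_indices": [...], "atac_batch_indices": [...]} names
    which batches export which modality; truth.batch_of must assign every
    cell to exactly one batch. Returns the unmatched OmicsBatch list (RNA
    batches first, in batch order).
    """
    rng = np.random.default_rng(seed)
    if truth.batch_of is None:
        raise ValueError("truth.batch_of is not set")
    batches = np.unique(truth.batch_of)
    if any(not 0 < e <= 1 for e in capture_eff):
        raise ValueError("capture_eff must be in (0, 1]")
    G = truth.rna_counts.shape[1]
    out: list[OmicsBatch] = []
    for which, modality in (("rna_batch_indices", "RNA"),
                            ("atac_batch_indices", "ATAC")):
        for bi in keep[which]:
            idx = np.flatnonzero(truth.batch_of == bi)
            cell_ids = [f"batch{bi}_cell{i}" for i in idx]
            if modality == "RNA":
                X = rng.binomial(truth.rna_counts[idx].astype(int),
                                 capture_eff[bi]).astype(float)
                if batch_effect_sd > 0:
                    factors = rng.lognormal(0.0, batch_effect_sd, size=G)
                    X = np.round(X * factors)
                fids = list(truth.true_gam.gene_ids)
            else:
                X = truth.atac_counts[idx].copy()
                if atac_flip > 0:
                    flips = rng.random(X.shape) < atac_flip
                    X = np.abs(X - flips.astype(float))
                fids = list(truth.true_gam.region_ids)
            out.append(OmicsBatch(X, modality, cell_ids, fids,
                                  batch_id=f"batch{bi}"))
    return out


# ---------------------------------------------------------------------------
# presets and the one-call generator
# ---------------------------------------------------------------------------

def preset_tree(name: str, cells_per_batch: int = 1500,
                n_batches: int = 2) -> TrajectoryTree:
    """Named trajectory topologies at the package's standard sizes.

    linear: one edge. bifurcating: trunk + 2 leaves (3 branches).
    trifurcating: trunk + 3 leaves (4 branches). small_branch: trifurcating
    with one short, sparsely populated branch. clusters: star of zero-length
    tight arms (discrete populations). imbalanced: trifurcating sized for a
    1486-cell ATAC batch vs a 757-cell RNA batch.
    """
    # Branch lengths and cell allocations are deliberately unequal: real
    # differentiation trees have arms of different durations and sizes, and
    # the asymmetry is what lets a distribution-matching merge identify
    # which arm is which across modalities.
    total = cells_per_batch * n_batches

    def alloc(fracs):
        ns = [int(total * f) for f in fracs]
        ns[0] += total - sum(ns)
        return ns

    if name == "linear":
        return TrajectoryTree([("root", "1", 1.0, total)], "root")
    if name == "bifurcating":
        ns = alloc([0.40, 0.25, 0.35])
        return TrajectoryTree([
            ("root", "m", 1.0, ns[0]),
            ("m", "a", 0.7, ns[1]),
            ("m", "b", 1.4, ns[2]),
        ], "root")
    if name == "trifurcating":
        ns = alloc([0.40, 0.15, 0.20, 0.25])
        return TrajectoryTree([
            ("root", "m", 1.0, ns[0]),
            ("m", "a", 0.6, ns[1]),
            ("m", "b", 1.0, ns[2]),
            ("m", "c", 1.5, ns[3]),
        ], "root")
    if name == "small_branch":
        n_small = max(total // 15, 1)  # short sparse branch
        rest = total - n_small
        ns = alloc([0.0, 0.0, 0.0, 0.0])  # unused; computed below
        n_trunk = int(rest * 0.45)
        n_a = int(rest * 0.25)
        n_b = rest - n_trunk - n_a
        return TrajectoryTree([
            ("root", "m", 1.0, n_trunk),
            ("m", "a", 0.8, n_a),
            ("m", "b", 1.4, n_b),
            ("m", "c", 0.4, n_small),
        ], "root")
    if name == "clusters":
        ns = alloc([0.30, 0.30, 0.22, 0.18])
        return TrajectoryTree([
            ("root", f"c{i}", 4.0, ns[i]) for i in range(4)
        ], "root")
    if name == "imbalanced":
        total = 1486 + 757
        ns = alloc([0.40, 0.15, 0.20, 0.25])
        return TrajectoryTree([
            ("root", "m", 1.0, ns[0]),
            ("m", "a", 0.6, ns[1]),
            ("m", "b", 1.0, ns[2]),
            ("m", "c", 1.5, ns[3]),
        ], "root")
    raise ValueError(f"unknown preset {name!r}")


def simulate_joint(tree: TrajectoryTree, n_genes: int = 100,
                   n_regions: int = 400, v: int = 20, step_sd: float = 1.0,
                   links_per_gene: int = 3, atac_noise: float = 0.1,
                   seed: int = 0, cluster_mode: bool = False
                   ) -> SimulationTruth:
    """Matched joint profiles for every cell of the tree."""
    rng = np.random.default_rng(seed)
    ids, pt, branch = simulate_identities(tree, v=v, step_sd=step_sd,
                                          seed=int(rng.integers(2**31)))
    if cluster_mode:
        # collapse each branch's cells onto its endpoint identity + jitter
        for b in np.unique(branch):
            m = branch == b
            ids[m] = ids[m].mean(axis=0) + 0.05 * np.random.default_rng(
                abs(hash(b)) % 2**31).normal(size=ids[m].shape)
    atac, region_ids = simulate_atac(ids, n_regions, noise=atac_noise,
                                     seed=int(rng.integers(2**31)))
    gam = random_gam(n_regions, n_genes, links_per_gene,
                     seed=int(rng.integers(2**31)))
    kin = base_kinetics(ids, n_genes, seed=int(rng.integers(2**31)))
    rna = simulate_rna(atac, gam, kin, seed=int(rng.integers(2**31)))
    return SimulationTruth(rna, atac, gam, pt, branch, ids, region_ids, kin)


def assign_batches(truth: SimulationTruth, n_batches: int = 2,
                   seed: int = 0,
                   sizes: list[int] | None = None) -> SimulationTruth:
    """Randomly assign every cell to a batch; balanced unless sizes given."""
    rng = np.random.default_rng(seed)
    n = truth.rna_counts.shape[0]
    if sizes is not None:
        if sum(sizes) != n:
            raise ValueError("sizes must sum to the cell count")
        batch = np.repeat(np.arange(len(sizes)), sizes)
    else:
        batch = np.repeat(np.arange(n_batches), int(np.ceil(n / n_batches)))[:n]
    rng.shuffle(batch)
    truth.batch_of = batch
    return truth
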