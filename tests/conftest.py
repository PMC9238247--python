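import numpy as np
import pytest

from trajalign.io import GeneActivityMatrix, GenomicInterval, OmicsBatch


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_rna_batch(rng):
    counts = rng.poisson(3.0, size=(20, 12)).astype(float)
    counts[0] += 1  # guard against a zero library
    return OmicsBatch(counts, "RNA",
                      [f"c{i}" for i in range(20)],
                      [f"g{j}" for j in range(12)], "rna0")


@pytest.fixture
def small_atac_batch(rng):
    counts = (rng.random((20, 15)) < 0.3).astype(float) * rng.poisson(
        2.0, size=(20, 15))
    counts[:, 0] += 1  # keep at least one open region per cell
    return OmicsBatch(counts, "ATAC",
                      [f"c{i}" for i in range(20)],
                      [f"r{j}" for j in range(15)], "atac0")


@pytest.fixture
def small_gam(rng):
    A = (rng.random((15, 12)) < 0.3).astype(float)
    A[0, 0] = 1  # no empty matrix
    return GeneActivityMatrix(A, [f"r{j}" for j in range(15)],
                              [f"g{j}" for j in range(12)])


def make_genes():
    return [
        GenomicInterval("chr1", 10_000, 15_000, "+", "geneA"),
        GenomicInterval("chr1", 40_000, 45_000, "-", "geneB"),
        GenomicInterval("chr2", 5_000, 9_000, "+", "geneC"),
    ]
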