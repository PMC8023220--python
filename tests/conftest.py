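import numpy as np
import pandas as pd
import pytest

from trilayer.config import RunConfig
from trilayer.io import ExpressionMatrix, GeneModel, SampleMeta


def make_matrix(arrays: dict[str, np.ndarray], metas: list[SampleMeta], genes=None):
    """Build an ExpressionMatrix from {sample_id: counts} columns."""
    n = len(next(iter(arrays.values())))
    genes = genes if genes is not None else [f"g{i}" for i in range(n)]
    df = pd.DataFrame(arrays, index=pd.Index(genes, name="gene_id"))
    return ExpressionMatrix(df[[m.sample_id for m in metas]], metas)


def nb_counts(rng: np.random.Generator, mean, disp, size) -> np.ndarray:
    """Gamma-Poisson draws with var = mean + disp * mean^2 (test oracle)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    lam = rng.gamma(1.0 / disp, mean * disp)
    return rng.poisson(lam)


def two_group_matrices(rng, n_genes, reps, mean_a, mean_b, disp,
                       genotype_a="P1", genotype_b="P2", assay="mrna_input"):
    metas, cols = [], {}
    for geno, mean in ((genotype_a, mean_a), (genotype_b, mean_b)):
        for r in range(1, reps + 1):
            sid = f"{geno}_{r}"
            metas.append(SampleMeta(sid, geno, assay, r))
            cols[sid] = nb_counts(rng, mean, disp, (n_genes,))
    return make_matrix(cols, metas)


@pytest.fixture
def cfg():
    return RunConfig()


@pytest.fixture
def gene_plus():
    """3-exon plus-strand gene; coordinates chosen for hand-checkable
    transcript arithmetic: mature length 700, start codon at t=100,
    stop codon at t=599."""
    return GeneModel(
        gene_id="gplus",
        chrom="chr1",
        strand="+",
        exons=[(1000, 1200), (1400, 1700), (1900, 2100)],
        cds_start=1100,
        cds_end=2000,
    )


@pytest.fixture
def gene_minus():
    """Same geometry on the minus strand: the 5'UTR comes from the
    higher-coordinate side; start codon t=100, stop codon t=599."""
    return GeneModel(
        gene_id="gminus",
        chrom="chr1",
        strand="-",
        exons=[(1000, 1200), (1400, 1700), (1900, 2100)],
        cds_start=1100,
        cds_end=2000,
    )
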