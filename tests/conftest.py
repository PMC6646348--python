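import numpy as np
import pytest

from xchrom import Cohort, SampleRecord, SnpRecord, X_CODE


def make_cohort(genotypes, sexes, phenotypes=None, snp_ids=None, traits=None):
    """Small hand-built cohort from arrays of codes."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    phenotypes = phenotypes if phenotypes is not None else [-9] * n
    alleles = [("A", "G"), ("C", "T"), ("T", "G"), ("A", "C"), ("G", "C")]
    samples = [
        SampleRecord(f"S{i}", f"S{i}", sex=int(sexes[i]), phenotype=int(phenotypes[i]))
        for i in range(n)
    ]
    snps = [
        SnpRecord(
            chromosome=X_CODE,
            snp_id=(snp_ids[j] if snp_ids else f"rs{j + 1}"),
            bp_position=1000 + j,
            allele1=alleles[j % len(alleles)][0],
            allele2=alleles[j % len(alleles)][1],
        )
        for j in range(m)
    ]
    return Cohort(samples=samples, snps=snps, genotypes=genotypes, quantitative_phenotypes=traits)


def random_cohort(rng, n_min=2, n_max=25, m_min=1, m_max=5, miss_rate=0.1):
    """Random cohort with hemizygous-consistent male genotypes."""
    n = int(rng.integers(n_min, n_max + 1))
    m = int(rng.integers(m_min, m_max + 1))
    sexes = rng.choice([1, 2], size=n)
    g = np.empty((n, m), dtype=np.int8)
    for j in range(m):
        p = rng.uniform(0.1, 0.5)
        fem = sexes == 2
        g[fem, j] = rng.choice(3, size=fem.sum(), p=[(1 - p) ** 2, 2 * p * (1 - p), p**2])
        g[~fem, j] = 2 * rng.binomial(1, p, size=(~fem).sum())
    g[rng.random((n, m)) < miss_rate] = -1
    phenos = rng.choice([1, 2], size=n)
    return make_cohort(g, sexes, phenotypes=phenos)


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)
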