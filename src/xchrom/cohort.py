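"""Core containers for X-linked genotype data.

Genotype codes count copies of the A1 (minor) allele: 2 = A1/A1,
1 = A1/A2, 0 = A2/A2, :data:`MISSING` (-1) = no call.  Males at
non-pseudoautosomal X loci are hemizygous and are stored with the
homozygous codes {0, 2}; a male heterozygote code is representable (so
that raw files can be read faithfully) but is flagged by QC.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

MALE: int = 1
FEMALE: int = 2

CONTROL: int = 1
CASE: int = 2
PHENO_MISSING: int = -9

#: chromosome code used for the X chromosome in PLINK numeric coding
X_CODE: int = 23


@dataclass(frozen=True)
class SnpRecord:
    """One marker: map position and allele labels.

    ``allele1`` (A1) is the counted, minor allele; ``allele2`` (A2) the
    alternative allele.  ``genetic_distance`` is in morgans and is 0 for
    all markers in this pipeline.
    """

    chromosome: int
    snp_id: str
    bp_position: int
    allele1: str
    allele2: str
    genetic_distance: float = 0.0

    def __post_init__(self) -> None:
        if self.bp_position <= 0:
            raise ValueError(f"{self.snp_id}: bp_position must be positive")
        if self.allele1 == self.allele2:
            raise ValueError(f"{self.snp_id}: alleles must differ")


@dataclass(frozen=True)
class SampleRecord:
    """One individual: pedigree fields, sex and binary affection status.

    Sex is 1 for males and 2 for females; phenotype is 1 for controls,
    2 for cases, and -9 (or 0 on input) for missing.
    """

    family_id: str
    sample_id: str
    paternal_id: str = "0"
    maternal_id: str = "0"
    sex: int = FEMALE
    phenotype: int = PHENO_MISSING

    def __post_init__(self) -> None:
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"{self.sample_id}: sex must be 1 (male) or 2 (female)")
        if self.phenotype not in (CONTROL, CASE, PHENO_MISSING, 0):
            raise ValueError(f"{self.sample_id}: phenotype must be 1, 2, 0 or -9")
        if self.phenotype == 0:
            object.__setattr__(self, "phenotype", PHENO_MISSING)


@dataclass
class Cohort:
    """Samples, markers and the genotype matrix, plus optional traits.

    ``genotypes`` is an ``(n_samples, n_snps)`` int8 array of A1-allele
    counts with :data:`MISSING` for no-calls.  ``quantitative_phenotypes``
    is an optional DataFrame indexed like ``samples`` (one row per sample,
    NaN for missing trait values).
    """

    samples: list[SampleRecord]
    snps: list[SnpRecord]
    genotypes: np.ndarray
    quantitative_phenotypes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        ok = (self.genotypes == MISSING) | (
            (self.genotypes >= 0) & (self.genotypes <= 2)
        )
        if not ok.all():
            raise ValueError("genotype codes must be in {0, 1, 2, MISSING}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        sids = [s.snp_id for s in self.snps]
        if len(set(sids)) != len(sids):
            raise ValueError("snp ids must be unique")
        if self.quantitative_phenotypes is not None and len(
            self.quantitative_phenotypes
        ) != len(self.samples):
            raise ValueError("quantitative phenotype table must have one row per sample")

    # -- convenience views ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def sexes(self) -> np.ndarray:
        """Per-sample sex codes (1 male / 2 female)."""
        return np.array([s.sex for s in self.samples], dtype=np.int8)

    @property
    def is_male(self) -> np.ndarray:
        return self.sexes == MALE

    @property
    def is_female(self) -> np.ndarray:
        return self.sexes == FEMALE

    def affection(self) -> np.ndarray:
        """Binary affection as float 0 (control) / 1 (case) with NaN missing."""
        pheno = np.array([s.phenotype for s in self.samples], dtype=float)
        y = np.full(self.n_samples, np.nan)
        y[pheno == CONTROL] = 0.0
        y[pheno == CASE] = 1.0
        return y

    def snp_index(self, snp_id: str) -> int:
        for i, s in enumerate(self.snps):
            if s.snp_id == snp_id:
                return i
        raise KeyError(snp_id)

    def genotype_frame(self) -> pd.DataFrame:
        """Genotypes as a samples x SNPs DataFrame (NaN for missing)."""
        g = self.genotypes.astype(float)
        g[g == MISSING] = np.nan
        return pd.DataFrame(g, index=self.sample_ids, columns=self.snp_ids)

    def subset_snps(self, keep: list[str]) -> "Cohort":
        """New cohort restricted to ``keep`` (original SNP order)."""
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.snps) if s.snp_id in keep_set]
        return Cohort(
            samples=list(self.samples),
            snps=[self.snps[i] for i in idx],
            genotypes=self.genotypes[:, idx].copy(),
            quantitative_phenotypes=(
                None
                if self.quantitative_phenotypes is None
                else self.quantitative_phenotypes.copy()
            ),
        )

    def copy(self) -> "Cohort":
        return Cohort(
            samples=list(self.samples),
            snps=list(self.snps),
            genotypes=self.genotypes.copy(),
            quantitative_phenotypes=(
                None
                if self.quantitative_phenotypes is None
                else self.quantitative_phenotypes.copy()
            ),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.snps == other.snps
            and np.array_equal(self.genotypes, other.genotypes)
        )


def cohorts_equivalent(a: Cohort, b: Cohort) -> bool:
    """Genetic equality up to per-SNP allele orientation.

    Text pedigree files store allele characters, not which allele is
    counted, so a round trip may legitimately come back with A1 and A2
    swapped at a SNP (codes complemented).  Two cohorts are equivalent
    when samples match and every genotype denotes the same allele pair.
    """
    if a.samples != b.samples or a.n_snps != b.n_snps:
        return False
    for j, (sa, sb) in enumerate(zip(a.snps, b.snps)):
        ga, gb = a.genotypes[:, j], b.genotypes[:, j]
        same_meta = (
            sa.chromosome == sb.chromosome
            and sa.snp_id == sb.snp_id
            and sa.bp_position == sb.bp_position
        )
        if not same_meta:
            return False
        if (sa.allele1, sa.allele2) == (sb.allele1, sb.allele2):
            if not np.array_equal(ga, gb):
                return False
        elif (sa.allele1, sa.allele2) == (sb.allele2, sb.allele1):
            flipped = np.where(gb == MISSING, MISSING, 2 - gb).astype(np.int8)
            if not np.array_equal(ga, flipped):
                return False
        else:
            # one side may carry a placeholder allele for a monomorphic SNP
            observed_a = set(np.unique(ga[ga != MISSING]))
            if observed_a <= {0} or observed_a <= {2}:
                continue
            return False
    return True
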