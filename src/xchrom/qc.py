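"""X-specific genotype quality control.

The battery reflects how QC differs on the X chromosome from autosomes:
call rates are computed per sex (male hemizygotes fail more often on
array platforms), differential missingness between the sexes is itself a
test, allele frequencies weight females twice, Hardy-Weinberg
equilibrium is testable only in females, and a male heterozygote call is
impossible and flags an upstream calling error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CASE, CONTROL, FEMALE, MALE, MISSING, Cohort

logger = logging.getLogger(__name__)


class Stratum(str, Enum):
    """Affection stratum of a per-SNP summary (Table-style TEST column)."""

    ALL = "ALL"
    AFF = "AFF"
    UNAFF = "UNAFF"


@dataclass(frozen=True)
class MissResult:
    """Per-SNP missingness by sex, with the male-female differential test."""

    snp_id: str
    miss_freq_males: float
    miss_freq_females: float
    p_diff: float | None = None

    @property
    def miss_diff(self) -> float:
        return self.miss_freq_males - self.miss_freq_females


@dataclass(frozen=True)
class SexFreqResult:
    """Sex-stratified A1 frequencies with the female-vs-male Fisher test."""

    snp_id: str
    maf_all: float
    maf_females: float
    maf_males: float
    odds_ratio: float
    p: float


@dataclass(frozen=True)
class HweResult:
    """Female genotype counts with exact Hardy-Weinberg test results."""

    snp_id: str
    stratum: Stratum
    counts: tuple[int, int, int]  # (n_A1A1, n_het, n_A2A2)
    o_het: float
    e_het: float
    p: float


@dataclass
class QCReport:
    """Every filter decision made by :func:`apply_qc`, with statistics."""

    thresholds: "QCThresholds"
    decisions: pd.DataFrame  # one row per (snp, criterion): statistic, threshold, pass
    excluded_snps: list[str]
    male_het_incidents: list[tuple[str, str]]

    def failed(self, snp_id: str) -> bool:
        return snp_id in self.excluded_snps


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; set a field to None to disable that criterion.

    Defaults follow published X-chromosome QC guidance: female
    missingness at most 2%, sex-differential missingness exact-test
    p >= 1e-7, minor-allele frequency at least 1%, and exact HWE p >=
    1e-4 evaluated in control females.
    """

    female_miss_max: float | None = 0.02
    diff_miss_p_min: float | None = 1e-7
    maf_min: float | None = 0.01
    hwe_p_min: float | None = 1e-4
    sanitize_male_hets: bool = True


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------


def _sex_missing_counts(cohort: Cohort) -> tuple[np.ndarray, np.ndarray, int, int]:
    male, female = cohort.is_male, cohort.is_female
    n_m, n_f = int(male.sum()), int(female.sum())
    if n_m == 0 or n_f == 0:
        raise ValueError("both sexes must be present to stratify missingness")
    miss = cohort.genotypes == MISSING
    return miss[male].sum(axis=0), miss[female].sum(axis=0), n_m, n_f


def missing_by_sex(cohort: Cohort) -> list[MissResult]:
    """Per-SNP missing-call proportion among males and among females."""
    miss_m, miss_f, n_m, n_f = _sex_missing_counts(cohort)
    return [
        MissResult(snp.snp_id, miss_m[j] / n_m, miss_f[j] / n_f)
        for j, snp in enumerate(cohort.snps)
    ]


def diff_missing_test(cohort: Cohort) -> list[MissResult]:
    """Two-sided Fisher exact test of missingness-by-sex per SNP.

    The 2x2 table is (missing, called) x (male, female) — the PLINK
    ``test-missing`` procedure with sex standing in for phenotype.
    """
    miss_m, miss_f, n_m, n_f = _sex_missing_counts(cohort)
    out = []
    for j, snp in enumerate(cohort.snps):
        table = [[miss_m[j], n_m - miss_m[j]], [miss_f[j], n_f - miss_f[j]]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        out.append(MissResult(snp.snp_id, miss_m[j] / n_m, miss_f[j] / n_f, p))
    return out


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


def _allele_counts(
    genotypes: np.ndarray, is_male: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(female A1, female total, male A1, male total) allele counts per SNP.

    Females contribute two alleles per called genotype; hemizygous males
    one.  A male heterozygote (calling error not yet sanitized) is
    counted as half an A1 copy of his single allele; QC flags it
    separately.
    """
    g = genotypes
    called = g != MISSING
    fem = ~is_male[:, None] & called
    mal = is_male[:, None] & called
    f_a1 = (np.where(fem, g, 0)).sum(axis=0)
    f_tot = 2 * fem.sum(axis=0)
    m_a1 = (np.where(mal, g, 0) / 2.0).sum(axis=0)
    m_tot = mal.sum(axis=0)
    return f_a1, f_tot, m_a1, m_tot


def sex_allele_freq_test(cohort: Cohort) -> list[SexFreqResult]:
    """A1 frequency per sex with a Fisher exact test of equality.

    The odds ratio is oriented female-versus-male: OR > 1 means the A1
    allele is more frequent in females.
    """
    f_a1, f_tot, m_a1, m_tot = _allele_counts(cohort.genotypes, cohort.is_male)
    out = []
    for j, snp in enumerate(cohort.snps):
        if f_tot[j] == 0 or m_tot[j] == 0:
            raise ValueError(f"{snp.snp_id}: a sex has zero called alleles")
        fa, ma = int(round(f_a1[j])), int(round(m_a1[j]))
        table = [[fa, int(f_tot[j]) - fa], [ma, int(m_tot[j]) - ma]]
        odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
        out.append(
            SexFreqResult(
                snp_id=snp.snp_id,
                maf_all=(f_a1[j] + m_a1[j]) / (f_tot[j] + m_tot[j]),
                maf_females=f_a1[j] / f_tot[j],
                maf_males=m_a1[j] / m_tot[j],
                odds_ratio=float(odds_ratio),
                p=float(p),
            )
        )
    return out


def maf_by_group(
    cohort: Cohort,
    grouping: Mapping[str, str] | Callable[[str], str] | None = None,
) -> pd.DataFrame:
    """A1 frequency per SNP within sample groups (x2 female / x1 male).

    ``grouping`` maps sample id to a group label; by default samples are
    grouped by affection status (CASE / CONTROL / MISSING).  The counted
    allele stays the cohort-wide A1, so group frequencies are comparable.
    """
    if grouping is None:
        labels = {
            s.sample_id: {CASE: "CASE", CONTROL: "CONTROL"}.get(s.phenotype, "MISSING")
            for s in cohort.samples
        }
    elif callable(grouping):
        labels = {s.sample_id: grouping(s.sample_id) for s in cohort.samples}
    else:
        labels = dict(grouping)

    lab = np.array([labels[s.sample_id] for s in cohort.samples])
    groups = sorted(set(lab))
    freq = np.full((cohort.n_snps, len(groups)), np.nan)
    for k, gname in enumerate(groups):
        mask = lab == gname
        if not mask.any():
            raise ValueError(f"empty group: {gname}")
        f_a1, f_tot, m_a1, m_tot = _allele_counts(
            cohort.genotypes[mask], cohort.is_male[mask]
        )
        tot = f_tot + m_tot
        with np.errstate(invalid="ignore"):
            freq[:, k] = (f_a1 + m_a1) / tot
    return pd.DataFrame(freq, index=cohort.snp_ids, columns=groups)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (females)
# ---------------------------------------------------------------------------


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg p-value for one biallelic genotype triple.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts (same parity as the rare-allele count)
    whose conditional probability does not exceed that of the observed
    count — the two-sided exact test of Wigginton, Cutler & Abecasis.
    Computed with the standard ratio recurrence for numerical stability.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one genotype required")
    rare = 2 * min(n_hom1, n_hom2) + n_het
    if rare == 0:
        return 1.0

    # unnormalized probabilities over all het counts with rare's parity
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}
    het, cur = mid, 1.0
    while het > 1:
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        cur *= het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
        probs[het] = cur
    het, cur = mid, 1.0
    while het <= rare - 2:
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        cur *= 4.0 * hom_r * hom_c / ((het + 2) * (het + 1))
        het += 2
        probs[het] = cur

    total = sum(probs.values())
    obs = probs[n_het]
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


def hwe_exact_female(
    n_hom1: int,
    n_het: int,
    n_hom2: int,
    snp_id: str = "",
    stratum: Stratum = Stratum.ALL,
) -> HweResult:
    """Exact HWE test on female genotype counts ``(A1A1, het, A2A2)``.

    Observed heterozygosity is the het proportion; expected is
    ``2p(1-p)`` at the sample A1 frequency ``p`` of the same counts.
    """
    n = n_hom1 + n_het + n_hom2
    p_a1 = (2 * n_hom1 + n_het) / (2 * n) if n else math.nan
    return HweResult(
        snp_id=snp_id,
        stratum=stratum,
        counts=(n_hom1, n_het, n_hom2),
        o_het=n_het / n if n else math.nan,
        e_het=2 * p_a1 * (1 - p_a1),
        p=hwe_exact_p(n_hom1, n_het, n_hom2),
    )


def female_genotype_counts(
    cohort: Cohort, snp_index: int, stratum: Stratum = Stratum.ALL
) -> tuple[int, int, int]:
    """Female (A1A1, het, A2A2) counts at one SNP, optionally by affection."""
    mask = cohort.is_female
    pheno = np.array([s.phenotype for s in cohort.samples])
    if stratum is Stratum.AFF:
        mask = mask & (pheno == CASE)
    elif stratum is Stratum.UNAFF:
        mask = mask & (pheno == CONTROL)
    g = cohort.genotypes[mask, snp_index]
    return (int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum()))


def hwe_table(cohort: Cohort, strata: Sequence[Stratum] = tuple(Stratum)) -> list[HweResult]:
    """Exact HWE results for every SNP and requested affection stratum."""
    out = []
    for j, snp in enumerate(cohort.snps):
        for st in strata:
            hom1, het, hom2 = female_genotype_counts(cohort, j, st)
            out.append(hwe_exact_female(hom1, het, hom2, snp.snp_id, st))
    return out


# ---------------------------------------------------------------------------
# Male heterozygotes and filter application
# ---------------------------------------------------------------------------


def male_het_scan(
    cohort: Cohort, sanitize: bool = False
) -> tuple[list[tuple[str, str]], Cohort]:
    """List (sample_id, snp_id) male heterozygote calls.

    With ``sanitize`` a copy of the cohort with those calls set to
    missing is returned (and the incidents logged); otherwise the input
    cohort is returned unchanged.
    """
    rows, cols = np.nonzero(cohort.is_male[:, None] & (cohort.genotypes == 1))
    incidents = [
        (cohort.samples[i].sample_id, cohort.snps[j].snp_id)
        for i, j in zip(rows, cols)
    ]
    if not sanitize or not incidents:
        return incidents, cohort
    fixed = cohort.copy()
    fixed.genotypes[rows, cols] = MISSING
    for sample_id, snp_id in incidents:
        logger.warning("male heterozygote set to missing: %s at %s", sample_id, snp_id)
    return incidents, fixed


def apply_qc(
    cohort: Cohort, thresholds: QCThresholds | None = None
) -> tuple[Cohort, QCReport]:
    """Apply the per-SNP filter battery; a SNP failing any enabled
    criterion is removed.

    Criteria: female missingness <= ``female_miss_max``; differential
    missingness exact p >= ``diff_miss_p_min``; A1 minor-allele frequency
    >= ``maf_min``; exact HWE p in control (normal-BMI) females >=
    ``hwe_p_min``.
    """
    thresholds = thresholds or QCThresholds()

    incidents, cohort = male_het_scan(cohort, sanitize=thresholds.sanitize_male_hets)

    rows: list[dict] = []
    failed: dict[str, bool] = {s: False for s in cohort.snp_ids}

    def record(snp_id: str, criterion: str, stat: float, thr: float, ok: bool) -> None:
        rows.append(
            {
                "snp_id": snp_id,
                "criterion": criterion,
                "statistic": stat,
                "threshold": thr,
                "pass": bool(ok),
            }
        )
        if not ok:
            failed[snp_id] = True

    if thresholds.female_miss_max is not None:
        for r in missing_by_sex(cohort):
            record(
                r.snp_id,
                "female_missingness",
                r.miss_freq_females,
                thresholds.female_miss_max,
                r.miss_freq_females <= thresholds.female_miss_max,
            )
    if thresholds.diff_miss_p_min is not None:
        for r in diff_missing_test(cohort):
            record(
                r.snp_id,
                "differential_missingness",
                r.p_diff,
                thresholds.diff_miss_p_min,
                r.p_diff >= thresholds.diff_miss_p_min,
            )
    if thresholds.maf_min is not None:
        f_a1, f_tot, m_a1, m_tot = _allele_counts(cohort.genotypes, cohort.is_male)
        tot = f_tot + m_tot
        for j, snp in enumerate(cohort.snps):
            freq = (f_a1[j] + m_a1[j]) / tot[j] if tot[j] else 0.0
            maf = min(freq, 1 - freq)
            record(snp.snp_id, "maf", maf, thresholds.maf_min, maf >= thresholds.maf_min)
    if thresholds.hwe_p_min is not None:
        ctrl_f = cohort.is_female & (
            np.array([s.phenotype for s in cohort.samples]) == CONTROL
        )
        if not ctrl_f.any():
            raise ValueError("HWE criterion enabled but no control females present")
        for j, snp in enumerate(cohort.snps):
            hom1, het, hom2 = female_genotype_counts(cohort, j, Stratum.UNAFF)
            p = hwe_exact_p(hom1, het, hom2)
            record(snp.snp_id, "hwe_control_females", p, thresholds.hwe_p_min, p >= thresholds.hwe_p_min)

    excluded = [s for s in cohort.snp_ids if failed[s]]
    report = QCReport(
        thresholds=thresholds,
        decisions=pd.DataFrame(
            rows, columns=["snp_id", "criterion", "statistic", "threshold", "pass"]
        ),
        excluded_snps=excluded,
        male_het_incidents=incidents,
    )
    kept = [s for s in cohort.snp_ids if not failed[s]]
    return cohort.subset_snps(kept), report


# ---------------------------------------------------------------------------
# Report rendering (PLINK-style dialects)
# ---------------------------------------------------------------------------


def hwe_report_frame(results: Sequence[HweResult]) -> pd.DataFrame:
    """HWE results in the ``.hwe`` column dialect."""
    return pd.DataFrame(
        {
            "SNP": [r.snp_id for r in results],
            "TEST": [r.stratum.value for r in results],
            "GENO": [f"{a}/{b}/{c}" for a, b, c in (r.counts for r in results)],
            "O(HET)": [r.o_het for r in results],
            "E(HET)": [r.e_het for r in results],
            "P": [r.p for r in results],
        }
    )


def missing_report_frame(results: Sequence[MissResult]) -> pd.DataFrame:
    """Missingness results in the ``.missing`` column dialect."""
    return pd.DataFrame(
        {
            "SNP": [r.snp_id for r in results],
            "F_MISS_M": [r.miss_freq_males for r in results],
            "F_MISS_F": [r.miss_freq_females for r in results],
            "DIFF": [r.miss_diff for r in results],
            "P": [r.p_diff for r in results],
        }
    )


def freq_report_frame(results: Sequence[SexFreqResult]) -> pd.DataFrame:
    """Sex-stratified frequency results in the ``.frq`` column dialect."""
    return pd.DataFrame(
        {
            "SNP": [r.snp_id for r in results],
            "MAF_ALL": [r.maf_all for r in results],
            "MAF_F": [r.maf_females for r in results],
            "MAF_M": [r.maf_males for r in results],
            "OR": [r.odds_ratio for r in results],
            "P": [r.p for r in results],
        }
    )
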