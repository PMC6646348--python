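"""X-chromosome association tests.

Autosomal tests assume two allele copies per subject; on X, males are
hemizygous and most female cells silence one X copy (X-chromosome
inactivation, XCI).  The tests here follow Clayton's approach: code each
subject with a numeric allele dosage whose male values depend on the
XCI model assumed for the locus, stratify by sex, and combine the
per-stratum score contributions.

* ``clayton_s1`` — 1-df statistic on the additive dosage; on female-only
  binary data it coincides with the Cochran-Armitage trend statistic in
  its (N-1)-scaled (Mantel-extension) form.
* ``clayton_s2`` — 2-df extension adding a female dominance indicator.

Both accept binary (0/1) and quantitative phenotypes.  Sex-stratified
centring is what protects the tests from sex-specific allele
frequencies combining with unbalanced case/control sex ratios — the
situation where naive pooled tests inflate their type-I error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CASE, CONTROL, MALE, MISSING, Cohort


@dataclass(frozen=True)
class DosageVector:
    """Per-sample numeric dosage under a declared XCI model.

    ``x`` is the additive component: 0/1/2 for females and, for males,
    0/2 under ``"inactivation"`` or 0/1 under ``"escape"``.  ``h`` is the
    female-heterozygote dominance indicator (always 0 for males).
    Missing genotypes are NaN in both.
    """

    x: np.ndarray
    h: np.ndarray
    xci_model: str


@dataclass(frozen=True)
class ScoreTestResult:
    """A chi-square score statistic with df, p and the n used.

    ``chi2``/``p`` are None when the statistic is undefined (zero score
    variance); ``reason`` then says why.
    """

    chi2: float | None
    df: int
    p: float | None
    n: int
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.chi2 is not None


@dataclass(frozen=True)
class FisherResult:
    """A 2x2 Fisher exact test: odds ratio, two-sided p, table, n."""

    odds_ratio: float
    p: float
    table: tuple[tuple[int, int], tuple[int, int]]
    n: int


@dataclass(frozen=True)
class ClaytonResult:
    """Joint 1-df and 2-df results for one SNP/phenotype pair."""

    snp_id: str
    phenotype_name: str
    n: int
    chi2_1df: float | None
    p_1df: float | None
    chi2_2df: float | None
    df_2: int
    p_2df: float | None


# ---------------------------------------------------------------------------
# Dosage coding
# ---------------------------------------------------------------------------


def xci_code(
    genotypes: np.ndarray, sexes: np.ndarray, xci_model: str = "inactivation"
) -> DosageVector:
    """Code genotypes as numeric dosages under an XCI model.

    Females count A1 copies 0/1/2 under both models.  Hemizygous males
    carry 0 or 1 copy; under inactivation the expressed dose matches a
    female homozygote (codes 0/2), under escape both female copies are
    expressed so a male copy is half a female homozygote (codes 0/1).
    Male heterozygote codes are rejected — sanitize first.
    """
    if xci_model not in ("inactivation", "escape"):
        raise ValueError(f"unknown xci_model: {xci_model!r}")
    g = np.asarray(genotypes)
    sexes = np.asarray(sexes)
    male = sexes == MALE
    if np.any(male & (g == 1)):
        raise ValueError("male heterozygote encountered; sanitize genotypes first")
    x = g.astype(float)
    x[g == MISSING] = np.nan
    if xci_model == "escape":
        x[male & (g == 2)] = 1.0
    h = np.where(~male & (g == 1), 1.0, 0.0)
    h[g == MISSING] = np.nan
    return DosageVector(x=x, h=h, xci_model=xci_model)


# ---------------------------------------------------------------------------
# Stratified score tests
# ---------------------------------------------------------------------------


def _strata_contributions(
    columns: np.ndarray, y: np.ndarray, strata: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Score vector and its variance, summed over strata.

    Per stratum s: U_s = sum_i (y_i - ybar_s) * z_i for each dosage
    column z, and V_s = [sum_i (y_i - ybar_s)^2] * Cov_s(z) * n_s/(n_s-1)
    with Cov_s the within-stratum (population) covariance of the columns.
    Strata of size < 2 carry no information and are skipped.
    """
    k = columns.shape[1]
    U = np.zeros(k)
    V = np.zeros((k, k))
    n_used = 0
    for s in np.unique(strata):
        idx = strata == s
        n_s = int(idx.sum())
        if n_s < 2:
            continue
        ys = y[idx]
        zs = columns[idx]
        yc = ys - ys.mean()
        U += yc @ zs
        cov = np.cov(zs, rowvar=False, ddof=1).reshape(k, k)  # n/(n-1) factor
        V += (yc @ yc) * cov
        n_used += n_s
    return U, V, n_used


def clayton_s1(
    dosage: DosageVector | np.ndarray,
    phenotype: np.ndarray,
    sexes: np.ndarray,
) -> ScoreTestResult:
    """Clayton's 1-df sex-stratified score test on the additive dosage.

    Binary phenotypes enter as y in {0, 1}; quantitative phenotypes are
    used as-is.  Pairs with missing dosage or phenotype are excluded.
    The statistic is (sum_s U_s)^2 / (sum_s V_s), chi-square on 1 df
    under the null of no association in either sex.
    """
    x = dosage.x if isinstance(dosage, DosageVector) else np.asarray(dosage, float)
    y = np.asarray(phenotype, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y, strata = x[keep], y[keep], np.asarray(sexes)[keep]
    n = int(keep.sum())
    if n == 0 or np.unique(y).size < 2:
        return ScoreTestResult(None, 1, None, n, "phenotype constant or empty")
    U, V, n_used = _strata_contributions(x[:, None], y, strata)
    if V[0, 0] <= 0:
        return ScoreTestResult(None, 1, None, n, "zero score variance")
    chi2 = float(U[0] ** 2 / V[0, 0])
    return ScoreTestResult(chi2, 1, float(stats.chi2.sf(chi2, 1)), n)


def clayton_s2(
    dosage: DosageVector,
    phenotype: np.ndarray,
    sexes: np.ndarray,
) -> ScoreTestResult:
    """Clayton's 2-df test on (additive dosage, female dominance indicator).

    The statistic is U' V^- U with a generalized inverse; the degrees of
    freedom equal rank(V), so a cohort without informative female
    heterozygote variation degrades gracefully to 1 df.
    """
    y = np.asarray(phenotype, dtype=float)
    keep = np.isfinite(dosage.x) & np.isfinite(dosage.h) & np.isfinite(y)
    cols = np.column_stack([dosage.x[keep], dosage.h[keep]])
    y, strata = y[keep], np.asarray(sexes)[keep]
    n = int(keep.sum())
    if n == 0 or np.unique(y).size < 2:
        return ScoreTestResult(None, 2, None, n, "phenotype constant or empty")
    U, V, n_used = _strata_contributions(cols, y, strata)
    rank = int(np.linalg.matrix_rank(V)) if np.any(V) else 0
    if rank == 0:
        return ScoreTestResult(None, 0, None, n, "zero score variance")
    chi2 = float(U @ np.linalg.pinv(V, hermitian=True) @ U)
    return ScoreTestResult(chi2, rank, float(stats.chi2.sf(chi2, rank)), n)


def trend_test_counts(
    control_counts: tuple[int, int, int], case_counts: tuple[int, int, int]
) -> ScoreTestResult:
    """Trend test on a 2x3 genotype table, closed form from the counts.

    Scores the genotype columns 0/1/2 and computes
    ``T = (N-1) * U^2 / (SSY * SSX)`` — the Mantel-extension scaling of
    the Cochran-Armitage statistic, matching the score-test convention
    used throughout this package.
    """
    n_j = np.array(control_counts, dtype=float) + np.array(case_counts, dtype=float)
    r_j = np.array(case_counts, dtype=float)
    scores = np.array([0.0, 1.0, 2.0])
    n_tot, r_tot = n_j.sum(), r_j.sum()
    if n_tot == 0 or r_tot == 0 or r_tot == n_tot:
        return ScoreTestResult(None, 1, None, int(n_tot), "phenotype constant or empty")
    u = r_j @ scores - (r_tot / n_tot) * (n_j @ scores)
    ssx = n_j @ scores**2 - (n_j @ scores) ** 2 / n_tot
    ssy = r_tot * (n_tot - r_tot) / n_tot
    if ssx <= 0:
        return ScoreTestResult(None, 1, None, int(n_tot), "zero score variance")
    chi2 = float((n_tot - 1) * u**2 / (ssy * ssx))
    return ScoreTestResult(chi2, 1, float(stats.chi2.sf(chi2, 1)), int(n_tot))


def pooled_trend_test(x: np.ndarray, y: np.ndarray) -> ScoreTestResult:
    """Unstratified (single-stratum) trend-type score test on dosages.

    The naive pooled analysis of mixed-sex X data; kept for the
    operating-characteristic experiments that show how it inflates
    type-I error under sex-specific allele frequencies with unbalanced
    case/control sex ratios.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    return clayton_s1(x[keep], y[keep], np.zeros(int(keep.sum()), dtype=int))


def female_trend_test(
    cohort: Cohort, snp_id: str, phenotype: str = "affection"
) -> ScoreTestResult:
    """Conventional autosomal trend test on female data only.

    For the binary affection phenotype this is the closed-form 2x3 table
    statistic of :func:`trend_test_counts`; for a quantitative phenotype
    it is the female-stratum score test.  Males are ignored entirely.
    """
    j = cohort.snp_index(snp_id)
    fem = cohort.is_female
    g = cohort.genotypes[fem, j]
    if phenotype == "affection":
        pheno = np.array([s.phenotype for s in cohort.samples])[fem]
        called = g != MISSING
        ctrl = (pheno == CONTROL) & called
        case = (pheno == CASE) & called
        return trend_test_counts(
            tuple(int(((g == k) & ctrl).sum()) for k in (0, 1, 2)),
            tuple(int(((g == k) & case).sum()) for k in (0, 1, 2)),
        )
    y = _phenotype_vector(cohort, phenotype)[fem]
    x = g.astype(float)
    x[g == MISSING] = np.nan
    return clayton_s1(x, y, np.full(x.size, 2, dtype=int))


def male_allelic_test(
    cohort: Cohort, snp_id: str, phenotype: str = "affection"
) -> FisherResult:
    """Allele-based Fisher exact test in males (cases vs controls).

    Hemizygous males carry one allele each, so the 2x2 table of
    (case, control) x (A1, A2) allele counts is just a subject count.
    The odds ratio is case-versus-control odds of carrying A1.
    """
    if phenotype != "affection":
        raise ValueError("the male allelic test is defined for the binary phenotype")
    j = cohort.snp_index(snp_id)
    mal = cohort.is_male
    g = cohort.genotypes[mal, j]
    pheno = np.array([s.phenotype for s in cohort.samples])[mal]
    called = g != MISSING
    table = (
        (int(((g == 2) & (pheno == CASE) & called).sum()),
         int(((g == 0) & (pheno == CASE) & called).sum())),
        (int(((g == 2) & (pheno == CONTROL) & called).sum()),
         int(((g == 0) & (pheno == CONTROL) & called).sum())),
    )
    odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
    return FisherResult(float(odds_ratio), float(p), table, int(sum(map(sum, table))))


# ---------------------------------------------------------------------------
# Cohort-level drivers
# ---------------------------------------------------------------------------


def _phenotype_vector(cohort: Cohort, name: str) -> np.ndarray:
    if name == "affection":
        return cohort.affection()
    if (
        cohort.quantitative_phenotypes is None
        or name not in cohort.quantitative_phenotypes.columns
    ):
        raise KeyError(f"unknown phenotype: {name!r}")
    return cohort.quantitative_phenotypes[name].to_numpy(dtype=float)


def clayton_tests(
    cohort: Cohort,
    snp_id: str,
    phenotype: str = "affection",
    xci_model: str = "inactivation",
) -> ClaytonResult:
    """Run S1 and S2 for one SNP against one phenotype."""
    j = cohort.snp_index(snp_id)
    dosage = xci_code(cohort.genotypes[:, j], cohort.sexes, xci_model)
    y = _phenotype_vector(cohort, phenotype)
    s1 = clayton_s1(dosage, y, cohort.sexes)
    s2 = clayton_s2(dosage, y, cohort.sexes)
    return ClaytonResult(
        snp_id=snp_id,
        phenotype_name=phenotype,
        n=s1.n,
        chi2_1df=s1.chi2,
        p_1df=s1.p,
        chi2_2df=s2.chi2,
        df_2=s2.df,
        p_2df=s2.p,
    )


def assoc_table(
    cohort: Cohort,
    phenotypes: list[str] | None = None,
    xci_model: str = "inactivation",
) -> pd.DataFrame:
    """S1/S2 results for every SNP against each phenotype.

    ``n`` is pairwise-complete per (SNP, phenotype): subjects missing
    either the genotype or that phenotype are dropped for that cell
    only.  Columns follow the conventional report order.
    """
    if phenotypes is None:
        phenotypes = ["affection"]
        if cohort.quantitative_phenotypes is not None:
            phenotypes = list(cohort.quantitative_phenotypes.columns)
    rows = []
    for pheno in phenotypes:
        for snp in cohort.snps:
            r = clayton_tests(cohort, snp.snp_id, pheno, xci_model)
            rows.append(
                {
                    "Phenotype": pheno,
                    "SNP": r.snp_id,
                    "N": r.n,
                    "Chi.squared.1.df": r.chi2_1df,
                    "Chi.squared.2.df": r.chi2_2df,
                    "P.1df": r.p_1df,
                    "P.2df": r.p_2df,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "Phenotype",
            "SNP",
            "N",
            "Chi.squared.1.df",
            "Chi.squared.2.df",
            "P.1df",
            "P.2df",
        ],
    )


def dosage_regression(
    cohort: Cohort,
    snp_id: str,
    phenotype: str = "affection",
    covariates: list[str] | None = None,
    xci_model: str = "inactivation",
):
    """Covariate-adjusted regression on the XCI-coded dosage.

    A convenience around the dosage coding: logistic regression for the
    binary affection phenotype, ordinary least squares for quantitative
    traits, always adjusting for sex (male indicator) plus any
    ``covariates`` drawn from the quantitative phenotype table.  Returns
    the fitted statsmodels results object.
    """
    import statsmodels.api as sm

    j = cohort.snp_index(snp_id)
    dosage = xci_code(cohort.genotypes[:, j], cohort.sexes, xci_model)
    y = _phenotype_vector(cohort, phenotype)
    X = pd.DataFrame(
        {"dosage": dosage.x, "male": cohort.is_male.astype(float)},
        index=cohort.sample_ids,
    )
    for cov in covariates or []:
        X[cov] = _phenotype_vector(cohort, cov)
    keep = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    X = sm.add_constant(X.loc[keep])
    if phenotype == "affection":
        model = sm.Logit(y[keep], X)
    else:
        model = sm.OLS(y[keep], X)
    return model.fit(disp=0) if phenotype == "affection" else model.fit()
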