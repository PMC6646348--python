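"""Synthetic X-linked case-control cohorts.

Generates cohorts with the structure the analysis layer assumes:
hemizygous male genotypes, sex-specific allele frequencies, a female
heterozygote deficit (Hardy-Weinberg disequilibrium), sex-specific
missingness, and binary or quantitative phenotypes generated under an
XCI or escape dosage model.  The default configuration emulates a
children's obesity case-control cohort of 915 subjects (477 females /
438 males; 355F/302M cases, 122F/136M controls) genotyped at 8 X-linked
SNPs in the TNMD and SLC6A14 genes, with per-sex allele frequencies,
per-sex missingness rates and per-SNP heterozygote-deficit coefficients
calibrated to the summary tables of that study design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import (
    CASE,
    CONTROL,
    FEMALE,
    MALE,
    MISSING,
    X_CODE,
    Cohort,
    SampleRecord,
    SnpRecord,
)

DEFAULT_SEED = 1729

_RESAMPLE_CAP = 10_000


@dataclass(frozen=True)
class SnpSpec:
    """Generative parameters for one marker.

    ``p_f``/``p_m`` are the A1 allele frequencies in females and males.
    ``f`` is an inbreeding-style Hardy-Weinberg disequilibrium
    coefficient for females: heterozygote probability 2*p*q*(1-f), so
    f > 0 produces the heterozygote deficit seen on array-called X data.
    ``miss_f``/``miss_m`` are per-call missingness probabilities by sex.
    ``beta`` (additive, per dosage unit) and ``beta_dom`` (female
    heterozygote indicator) are log-odds or trait-unit effect sizes.
    """

    snp_id: str
    bp_position: int
    allele1: str
    allele2: str
    p_f: float
    p_m: float
    f: float = 0.0
    miss_f: float = 0.0
    miss_m: float = 0.0
    beta: float = 0.0
    beta_dom: float = 0.0

    def female_genotype_probs(self) -> tuple[float, float, float]:
        """(P(A2A2), P(het), P(A1A1)) for genotype codes (0, 1, 2)."""
        p, q, fc = self.p_f, 1 - self.p_f, self.f
        probs = (q * q + fc * p * q, 2 * p * q * (1 - fc), p * p + fc * p * q)
        if min(probs) < -1e-12:
            raise ValueError(
                f"{self.snp_id}: f={fc} gives negative genotype probabilities"
            )
        return tuple(max(0.0, v) for v in probs)  # type: ignore[return-value]


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic cohort.

    ``group_sex_counts`` fixes the recruitment margins as
    ``((controls_F, controls_M), (cases_F, cases_M))``.  Under the
    ``binary_logistic`` effect model affection is drawn from
    ``logit P(case) = alpha + beta*x + beta_dom*h + gamma*male`` and the
    draw is repeated per sex until the margins match; ``null`` assigns
    the group labels by count, independent of genotype;
    ``quantitative_linear`` adds a Gaussian trait
    ``y = beta*x + beta_dom*h + gamma*male + N(0, sigma)`` and assigns
    group labels as under ``null``.
    """

    snps: tuple[SnpSpec, ...]
    n_females: int = 477
    n_males: int = 438
    group_sex_counts: tuple[tuple[int, int], tuple[int, int]] = ((122, 136), (355, 302))
    effect_model: str = "null"  # null | binary_logistic | quantitative_linear
    xci_model: str = "inactivation"
    alpha: float | None = None  # logistic intercept; None = matched to margins
    gamma: float = 0.0  # sex effect (male indicator)
    sigma: float = 1.0  # trait noise sd
    trait_name: str = "trait"
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        (cf, cm), (af, am) = self.group_sex_counts
        if cf + af != self.n_females or cm + am != self.n_males:
            raise ValueError("group sex counts must sum to the per-sex totals")
        if self.effect_model not in ("null", "binary_logistic", "quantitative_linear"):
            raise ValueError(f"unknown effect model: {self.effect_model!r}")
        if self.xci_model not in ("inactivation", "escape"):
            raise ValueError(f"unknown xci_model: {self.xci_model!r}")
        for spec in self.snps:
            if not (0 < spec.p_f < 1 and 0 < spec.p_m < 1):
                raise ValueError(f"{spec.snp_id}: allele frequencies must be in (0,1)")
            spec.female_genotype_probs()  # validates f

    @property
    def n_samples(self) -> int:
        return self.n_females + self.n_males


@dataclass(frozen=True)
class TruthRecord:
    """What the generator actually drew, for downstream checks.

    Realized (pre-missingness) A1 frequencies per SNP and sex, the
    latent additive dosage matrix under the config's XCI model, and the
    (config, seed) pair everything is reproducible from.
    """

    config: SimConfig
    seed: int
    realized_p_f: np.ndarray
    realized_p_m: np.ndarray
    latent_dosage: np.ndarray


def simulate_cohort(config: SimConfig, seed: int | None = None) -> tuple[Cohort, TruthRecord]:
    """Draw one cohort from ``config``; all randomness flows from the seed.

    Sample order is females first then males.  Missingness is applied
    last, so the truth record's latent dosages are complete.
    """
    used_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    n_f, n_m, m = config.n_females, config.n_males, len(config.snps)
    female = np.zeros(n_f + n_m, dtype=bool)
    female[:n_f] = True

    genotypes = np.empty((n_f + n_m, m), dtype=np.int8)
    for j, spec in enumerate(config.snps):
        probs = spec.female_genotype_probs()
        genotypes[:n_f, j] = rng.choice(3, size=n_f, p=probs)
        genotypes[n_f:, j] = 2 * rng.binomial(1, spec.p_m, size=n_m)

    # latent dosage under the config's XCI model (no male hets by construction)
    x = genotypes.astype(float)
    if config.xci_model == "escape":
        x[~female[:, None] & (genotypes == 2)] = 1.0
    h = ((genotypes == 1) & female[:, None]).astype(float)

    betas = np.array([s.beta for s in config.snps])
    betas_dom = np.array([s.beta_dom for s in config.snps])
    lin = x @ betas + h @ betas_dom + config.gamma * (~female)

    (cf, cm), (af, am) = config.group_sex_counts
    if config.effect_model == "binary_logistic":
        affected = np.empty(n_f + n_m, dtype=bool)
        for idx, target in (
            (np.flatnonzero(female), af),
            (np.flatnonzero(~female), am),
        ):
            # margins are fixed by recruitment, so the intercept (and with
            # it any sex main effect) is centred per sex unless overridden
            alpha = (
                config.alpha
                if config.alpha is not None
                else float(logit(target / idx.size)) - float(np.mean(lin[idx]))
            )
            prob = expit(alpha + lin)
            for attempt in range(_RESAMPLE_CAP):
                draw = rng.random(idx.size) < prob[idx]
                if int(draw.sum()) == target:
                    affected[idx] = draw
                    break
            else:
                raise RuntimeError(
                    f"could not match group sex counts in {_RESAMPLE_CAP} draws"
                )
    else:
        affected = np.zeros(n_f + n_m, dtype=bool)
        fem_idx = rng.permutation(np.flatnonzero(female))
        mal_idx = rng.permutation(np.flatnonzero(~female))
        affected[fem_idx[:af]] = True
        affected[mal_idx[:am]] = True

    traits = None
    if config.effect_model == "quantitative_linear":
        y = lin + rng.normal(0.0, config.sigma, size=n_f + n_m)
        traits = pd.DataFrame({config.trait_name: y})

    realized_p_f = (genotypes[:n_f].sum(axis=0)) / (2.0 * n_f) if n_f else np.full(m, np.nan)
    realized_p_m = (genotypes[n_f:].sum(axis=0)) / (2.0 * n_m) if n_m else np.full(m, np.nan)
    truth = TruthRecord(
        config=config,
        seed=used_seed,
        realized_p_f=realized_p_f,
        realized_p_m=realized_p_m,
        latent_dosage=x,
    )

    # missingness applied last, independent Bernoulli per (sample, SNP) by sex
    miss_f = np.array([s.miss_f for s in config.snps])
    miss_m = np.array([s.miss_m for s in config.snps])
    u = rng.random(genotypes.shape)
    drop = np.where(female[:, None], u < miss_f, u < miss_m)
    genotypes[drop] = MISSING

    samples = []
    for i in range(n_f + n_m):
        sid = f"F{i + 1:04d}" if female[i] else f"M{i - n_f + 1:04d}"
        samples.append(
            SampleRecord(
                family_id=sid,
                sample_id=sid,
                sex=FEMALE if female[i] else MALE,
                phenotype=CASE if affected[i] else CONTROL,
            )
        )
    snps = [
        SnpRecord(
            chromosome=X_CODE,
            snp_id=s.snp_id,
            bp_position=s.bp_position,
            allele1=s.allele1,
            allele2=s.allele2,
        )
        for s in config.snps
    ]
    if traits is not None:
        traits.index = [s.sample_id for s in samples]
    cohort = Cohort(samples=samples, snps=snps, genotypes=genotypes, quantitative_phenotypes=traits)
    return cohort, truth


# ---------------------------------------------------------------------------
# Default study-shaped configuration
# ---------------------------------------------------------------------------

#: Per-SNP defaults emulating the 8-marker TNMD / SLC6A14 panel:
#: sex-specific A1 frequencies and per-sex missingness rates as reported
#: for that panel, and heterozygote-deficit coefficients f back-computed
#: from the reported female genotype counts (f = 1 - O(HET)/E(HET)).
DEFAULT_SNPS: tuple[SnpSpec, ...] = (
    SnpSpec("rs11798018", 100584572, "A", "C", 0.26, 0.27, 0.015, 0.04, 0.11),
    SnpSpec("rs5966709", 100589508, "T", "G", 0.32, 0.31, 0.161, 0.004, 0.06),
    SnpSpec("rs4828037", 100590686, "C", "T", 0.34, 0.33, 0.168, 0.01, 0.06),
    SnpSpec("rs2073162", 100594019, "A", "G", 0.45, 0.42, 0.270, 0.008, 0.08),
    SnpSpec("rs2073163", 100594053, "C", "T", 0.46, 0.43, 0.314, 0.09, 0.14),
    SnpSpec("rs4828038", 100596678, "T", "C", 0.45, 0.42, 0.278, 0.002, 0.07),
    SnpSpec("rs1155974", 100598283, "T", "C", 0.44, 0.42, 0.270, 0.002, 0.08),
    SnpSpec("rs2011162", 116459132, "C", "G", 0.37, 0.30, 0.182, 0.02, 0.07),
)


def default_config(**overrides) -> SimConfig:
    """The study-shaped default: 915 children, 8 X-linked SNPs.

    Margins 477 females / 438 males with 122F/136M controls and
    355F/302M cases; null effect model.  Keyword overrides are applied
    with :func:`dataclasses.replace` semantics.
    """
    cfg = SimConfig(snps=DEFAULT_SNPS)
    return replace(cfg, **overrides) if overrides else cfg


def apply_exact_missingness(cohort: Cohort, specs: tuple[SnpSpec, ...] | None = None) -> Cohort:
    """Deterministic missingness fixture: exact per-sex no-call counts.

    Sets the first ``floor(rate * n_sex)`` samples of each sex to
    missing at each SNP, so the realized per-sex missing frequencies
    match the configured rates to within one call, with no randomness.
    """
    specs = specs if specs is not None else DEFAULT_SNPS
    if len(specs) != cohort.n_snps:
        raise ValueError("one SnpSpec per cohort SNP required")
    out = cohort.copy()
    fem_idx = np.flatnonzero(cohort.is_female)
    mal_idx = np.flatnonzero(cohort.is_male)
    for j, spec in enumerate(specs):
        k_f = math.floor(spec.miss_f * fem_idx.size)
        k_m = math.floor(spec.miss_m * mal_idx.size)
        out.genotypes[fem_idx[:k_f], j] = MISSING
        out.genotypes[mal_idx[:k_m], j] = MISSING
    return out
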