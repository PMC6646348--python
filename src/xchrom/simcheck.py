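"""Monte-Carlo operating characteristics of the X association tests.

Repeatedly simulates cohorts from a :class:`~xchrom.simulate.SimConfig`,
applies a chosen battery of tests to a designated SNP, and reports
empirical rejection rates with their binomial uncertainty.  The bundled
scenarios encode the test-selection guidance the package implements:
the sex-stratified tests hold their nominal level even when sex-specific
allele frequencies meet an unbalanced case/control sex ratio, while the
naive pooled trend test does not.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import (
    clayton_s1,
    clayton_s2,
    female_trend_test,
    male_allelic_test,
    pooled_trend_test,
    xci_code,
)
from .simulate import SimConfig, SnpSpec, default_config, simulate_cohort

KNOWN_TESTS = ("clayton_s1", "clayton_s2", "pooled_trend", "female_trend", "male_allelic")


@dataclass(frozen=True)
class ScenarioResult:
    """Empirical rejection rates of each test at each nominal alpha."""

    label: str
    rates: pd.DataFrame  # index: test, columns: alpha
    n_reps: int
    n_defined: pd.Series  # reps on which each test was defined
    seed: int

    def band(self, alpha: float, conf: float = 0.99) -> tuple[float, float]:
        """Binomial confidence band around the nominal level."""
        return binomial_band(alpha, self.n_reps, conf)


def binomial_band(alpha: float, n_reps: int, conf: float = 0.99) -> tuple[float, float]:
    """Normal-approximation band for an empirical rate at nominal alpha."""
    z = stats.norm.ppf(0.5 + conf / 2)
    half = z * np.sqrt(alpha * (1 - alpha) / n_reps)
    return (alpha - half, alpha + half)


def _test_pvalue(name: str, cohort, snp_id: str, xci_model: str) -> float | None:
    if name in ("clayton_s1", "clayton_s2", "pooled_trend"):
        j = cohort.snp_index(snp_id)
        dosage = xci_code(cohort.genotypes[:, j], cohort.sexes, xci_model)
        y = cohort.affection()
        if name == "clayton_s1":
            r = clayton_s1(dosage, y, cohort.sexes)
        elif name == "clayton_s2":
            r = clayton_s2(dosage, y, cohort.sexes)
        else:
            r = pooled_trend_test(dosage.x, y)
        return r.p
    if name == "female_trend":
        return female_trend_test(cohort, snp_id).p
    if name == "male_allelic":
        return male_allelic_test(cohort, snp_id).p
    raise ValueError(f"unknown test: {name!r}")


def run_scenario(
    config: SimConfig,
    tests: list[str] | tuple[str, ...] = ("clayton_s1", "clayton_s2"),
    alphas: tuple[float, ...] = (0.05, 0.01),
    n_reps: int = 2000,
    seed: int | None = None,
    label: str = "",
    snp_id: str | None = None,
) -> ScenarioResult:
    """Simulate ``n_reps`` cohorts and record per-test rejection rates.

    The designated test SNP defaults to the first SNP of the config.
    A test undefined on a replicate (e.g. a monomorphic draw) is skipped
    for that replicate; rates are computed over defined replicates, and
    a test undefined on more than 10% of them raises.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100 for stable rate estimates")
    for t in tests:
        if t not in KNOWN_TESTS:
            raise ValueError(f"unknown test: {t!r}")
    used_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    target = snp_id if snp_id is not None else config.snps[0].snp_id

    pvals: dict[str, list[float]] = {t: [] for t in tests}
    for _ in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        cohort, _truth = simulate_cohort(config, seed=rep_seed)
        for t in tests:
            p = _test_pvalue(t, cohort, target, config.xci_model)
            if p is not None:
                pvals[t].append(p)

    n_defined = pd.Series({t: len(pvals[t]) for t in tests})
    for t in tests:
        if n_defined[t] < 0.9 * n_reps:
            raise RuntimeError(
                f"test {t!r} undefined on {n_reps - n_defined[t]} of {n_reps} replicates"
            )
    rates = pd.DataFrame(
        {
            a: {t: float(np.mean(np.asarray(pvals[t]) < a)) for t in tests}
            for a in alphas
        }
    )
    return ScenarioResult(
        label=label or "scenario",
        rates=rates,
        n_reps=n_reps,
        n_defined=n_defined,
        seed=used_seed,
    )


# ---------------------------------------------------------------------------
# Bundled scenarios
# ---------------------------------------------------------------------------


def _one_snp_config(p_f: float, p_m: float, **cfg_overrides) -> SimConfig:
    spec = SnpSpec("snp1", 1_000_000, "A", "G", p_f=p_f, p_m=p_m)
    base = SimConfig(snps=(spec,))
    return replace(base, **cfg_overrides) if cfg_overrides else base


def bundled_scenarios() -> list[tuple[str, SimConfig]]:
    """The five labelled study scenarios used by the calibration harness.

    (a) balanced sex margins, equal sex frequencies, no effect — the
    null-calibration feed; (b) unbalanced margins (controls 80% female,
    cases 30% female) with sex-specific frequencies 0.37/0.30, no effect
    — the type-I inflation demonstration for pooled tests; (c) additive
    effect under X inactivation; (d) additive effect under escape;
    (e) female-dominance-only effect, where the 2-df test has the power
    advantage.
    """
    balanced = ((122, 136), (355, 302))
    scenarios = [
        (
            "balanced_null",
            _one_snp_config(0.30, 0.30, group_sex_counts=balanced, seed=101),
        ),
        (
            "unbalanced_sexfreq_null",
            _one_snp_config(
                0.37,
                0.30,
                n_females=403,
                n_males=512,
                group_sex_counts=((206, 52), (197, 460)),
                seed=102,
            ),
        ),
        (
            "xci_additive",
            replace(
                _one_snp_config(0.30, 0.30, group_sex_counts=balanced, seed=103),
                snps=(SnpSpec("snp1", 1_000_000, "A", "G", 0.30, 0.30, beta=0.30),),
                effect_model="binary_logistic",
                xci_model="inactivation",
            ),
        ),
        (
            "escape_additive",
            replace(
                _one_snp_config(0.30, 0.30, group_sex_counts=balanced, seed=104),
                snps=(SnpSpec("snp1", 1_000_000, "A", "G", 0.30, 0.30, beta=0.30),),
                effect_model="binary_logistic",
                xci_model="escape",
            ),
        ),
        (
            "dominance_only",
            replace(
                _one_snp_config(0.30, 0.30, group_sex_counts=balanced, seed=105),
                snps=(
                    SnpSpec("snp1", 1_000_000, "A", "G", 0.30, 0.30, beta_dom=0.50),
                ),
                effect_model="binary_logistic",
            ),
        ),
    ]
    return scenarios


def rates_report_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    """Long-format TSV-ready table of rejection rates across scenarios."""
    rows = []
    for r in results:
        for test in r.rates.index:
            for alpha in r.rates.columns:
                lo, hi = r.band(float(alpha))
                rows.append(
                    {
                        "scenario": r.label,
                        "test": test,
                        "alpha": float(alpha),
                        "rejection_rate": r.rates.loc[test, alpha],
                        "n_reps": r.n_reps,
                        "n_defined": int(r.n_defined[test]),
                        "band_low": lo,
                        "band_high": hi,
                        "seed": r.seed,
                    }
                )
    return pd.DataFrame(rows)
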