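"""QC battery: missingness, sex frequencies, exact HWE, filters."""

import math
from itertools import product

import numpy as np
import pytest

from xchrom import (
    MISSING,
    QCThresholds,
    Stratum,
    apply_qc,
    diff_missing_test,
    hwe_exact_female,
    hwe_exact_p,
    hwe_table,
    maf_by_group,
    male_het_scan,
    missing_by_sex,
    sex_allele_freq_test,
)
from xchrom.simulate import DEFAULT_SNPS, apply_exact_missingness, default_config, simulate_cohort

from conftest import make_cohort


# ---------------------------------------------------------------------------
# Independent enumeration oracles
# ---------------------------------------------------------------------------


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration (exact ints)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    weights = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    total = sum(weights.values())
    obs = weights[a]
    return sum(w for w in weights.values() if w <= obs) / total


def hwe_oracle(n_hom1, n_het, n_hom2):
    """Exact HWE p by enumerating the full conditional distribution with
    integer weights n! / (hom_r! het! hom_c!) * 2^het."""
    n = n_hom1 + n_het + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het
    weights = {}
    for het in range(rare % 2, min(rare, 2 * n - rare) + 1, 2):
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        if hom_r < 0 or hom_c < 0:
            continue
        weights[het] = (
            math.factorial(n)
            // (math.factorial(hom_r) * math.factorial(het) * math.factorial(hom_c))
            * 2**het
        )
    total = sum(weights.values())
    obs = weights[n_het]
    return sum(w for w in weights.values() if w <= obs) / total


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------


class TestMissingness:
    def test_no_missing_calls(self):
        cohort = make_cohort([[0, 1], [2, 0], [2, 2]], sexes=[1, 2, 2])
        assert all(
            r.miss_freq_males == 0 and r.miss_freq_females == 0
            for r in missing_by_sex(cohort)
        )

    def test_direct_count(self):
        """48 missing males of 438 gives male missing frequency 48/438."""
        g = np.zeros((438 + 477, 1), dtype=np.int8)
        g[:48, 0] = MISSING
        sexes = [1] * 438 + [2] * 477
        (r,) = missing_by_sex(make_cohort(g, sexes))
        assert r.miss_freq_males == pytest.approx(48 / 438)
        assert r.miss_freq_females == 0

    def test_rates_recovered_at_scale(self):
        """Bernoulli missingness estimates sit within 3 binomial SE."""
        cfg = default_config(
            n_females=20000,
            n_males=20000,
            group_sex_counts=((10000, 10000), (10000, 10000)),
        )
        cohort, _ = simulate_cohort(cfg, seed=99)
        for r, spec in zip(missing_by_sex(cohort), cfg.snps):
            for est, rate, n in (
                (r.miss_freq_females, spec.miss_f, 20000),
                (r.miss_freq_males, spec.miss_m, 20000),
            ):
                se = math.sqrt(max(rate * (1 - rate), 1e-9) / n)
                assert abs(est - rate) < 3 * se + 1e-9

    def test_identical_patterns_give_p_one(self):
        g = np.array([[MISSING], [0], [MISSING], [1]], dtype=np.int8)
        (r,) = diff_missing_test(make_cohort(g, sexes=[1, 1, 2, 2]))
        assert r.p_diff == pytest.approx(1.0)

    def test_p_matches_enumeration_oracle(self):
        """Males 5/45, females 1/49: p equals the two-sided tail sum."""
        g = np.full((100, 1), 0, dtype=np.int8)
        g[:5, 0] = MISSING  # males 5 missing / 45 called
        g[50, 0] = MISSING  # females 1 missing / 49 called
        (r,) = diff_missing_test(make_cohort(g, sexes=[1] * 50 + [2] * 50))
        assert r.p_diff == pytest.approx(fisher_oracle(5, 45, 1, 49), rel=1e-9)

    def test_doubling_cells_never_increases_p(self):
        """More data, same proportions: evidence cannot weaken."""
        for a, b, c, d in product(range(0, 7, 2), repeat=4):
            if (a + b) == 0 or (c + d) == 0:
                continue
            assert fisher_oracle(2 * a, 2 * b, 2 * c, 2 * d) <= fisher_oracle(a, b, c, d) + 1e-12


# ---------------------------------------------------------------------------
# Sex-specific allele frequencies
# ---------------------------------------------------------------------------


class TestSexAlleleFreq:
    def test_equal_frequencies_null(self):
        # 2 female AA + 2 female aa, 2 male A- + 2 male a-: p = 0.5 in both
        cohort = make_cohort([[2], [0], [2], [0], [2], [0], [2], [0]], sexes=[2] * 4 + [1] * 4)
        (r,) = sex_allele_freq_test(cohort)
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)
        assert r.maf_females == pytest.approx(r.maf_males)

    def test_reconstructed_study_counts(self):
        """Female 347/593 vs male 122/285 minor/major alleles: OR ~ 1.37."""
        from scipy.stats import fisher_exact

        odds_ratio, p = fisher_exact([[347, 593], [122, 285]])
        assert odds_ratio == pytest.approx(1.367, abs=0.05)
        assert p < 0.05
        assert p == pytest.approx(fisher_oracle(347, 593, 122, 285), rel=1e-9)

    def test_allele_swap_inverts_odds_ratio(self):
        g = np.array([[2], [1], [0], [0], [2], [0], [2], [2]], dtype=np.int8)
        sexes = [2, 2, 2, 2, 1, 1, 1, 1]
        (r,) = sex_allele_freq_test(make_cohort(g, sexes))
        swapped = np.where(g == MISSING, MISSING, 2 - g).astype(np.int8)
        (r2,) = sex_allele_freq_test(make_cohort(swapped, sexes))
        assert r2.odds_ratio == pytest.approx(1 / r.odds_ratio)
        assert r2.p == pytest.approx(r.p)

    def test_weighting_females_twice(self):
        # one female het (1 of 2 alleles) + one male carrier (1 of 1)
        cohort = make_cohort([[1], [2]], sexes=[2, 1])
        (r,) = sex_allele_freq_test(cohort)
        assert r.maf_females == pytest.approx(0.5)
        assert r.maf_males == pytest.approx(1.0)
        assert r.maf_all == pytest.approx(2 / 3)


class TestMafByGroup:
    def test_single_group_matches_overall(self):
        cohort = make_cohort(
            [[2], [1], [0], [2]], sexes=[2, 2, 1, 1], phenotypes=[2, 2, 2, 2]
        )
        (r,) = sex_allele_freq_test(cohort)
        table = maf_by_group(cohort)
        assert table.loc["rs1", "CASE"] == pytest.approx(r.maf_all)

    def test_male_only_group_is_carrier_proportion(self):
        cohort = make_cohort(
            [[2], [0], [2], [1]], sexes=[1, 1, 1, 2], phenotypes=[1, 1, 1, 2]
        )
        table = maf_by_group(cohort)
        assert table.loc["rs1", "CONTROL"] == pytest.approx(2 / 3)

    def test_groups_recover_configured_frequencies(self):
        cfg = default_config(
            n_females=10000,
            n_males=10000,
            group_sex_counts=((5000, 5000), (5000, 5000)),
        )
        cohort, _ = simulate_cohort(cfg, seed=5)
        table = maf_by_group(cohort)
        for j, spec in enumerate(cfg.snps):
            expect = (2 * spec.p_f + spec.p_m) / 3  # 2 female alleles : 1 male
            for grp in ("CASE", "CONTROL"):
                assert table.loc[spec.snp_id, grp] == pytest.approx(expect, abs=0.02)

    def test_unlabelled_sample_rejected(self):
        cohort = make_cohort([[1], [2]], sexes=[2, 2])
        with pytest.raises(KeyError):
            maf_by_group(cohort, {"S0": "A"})


# ---------------------------------------------------------------------------
# Exact HWE
# ---------------------------------------------------------------------------


class TestHweExact:
    @pytest.mark.parametrize(
        "counts, p, o_het, e_het",
        [
            ((34, 177, 249), 0.72, 0.38, 0.39),
            ((132, 172, 170), 4.59e-09, 0.36, 0.50),
            ((129, 148, 156), 6.92e-11, 0.34, 0.50),
            ((22, 42, 57), 0.01, 0.35, 0.46),
        ],
    )
    def test_reference_triples(self, counts, p, o_het, e_het):
        r = hwe_exact_female(*counts)
        assert r.p == pytest.approx(p, rel=0.1)
        assert r.o_het == pytest.approx(o_het, abs=0.006)
        assert r.e_het == pytest.approx(e_het, abs=0.006)

    @pytest.mark.parametrize("k", [1, 5, 40])
    def test_monomorphic_is_null(self, k):
        assert hwe_exact_p(k, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, k) == 1.0

    def test_allele_swap_symmetry(self, rng):
        for _ in range(50):
            a, h, b = (int(v) for v in rng.integers(0, 40, 3))
            if a + h + b == 0:
                continue
            assert hwe_exact_p(a, h, b) == pytest.approx(hwe_exact_p(b, h, a), rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 3)
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)

    def test_matches_enumeration_oracle_small_grid(self):
        """Exhaustive agreement with the integer-weight enumeration for
        all triples with total <= 12 (the full grid runs in acceptance)."""
        for n in range(1, 13):
            for a in range(n + 1):
                for h in range(n - a + 1):
                    b = n - a - h
                    assert hwe_exact_p(a, h, b) == pytest.approx(
                        hwe_oracle(a, h, b), rel=1e-9
                    )

    def test_hwe_table_strata(self):
        cohort, _ = simulate_cohort(default_config(), seed=11)
        results = hwe_table(cohort)
        assert len(results) == cohort.n_snps * 3
        by_key = {(r.snp_id, r.stratum): r for r in results}
        for snp in cohort.snp_ids:
            all_counts = np.array(by_key[(snp, Stratum.ALL)].counts)
            split = (
                np.array(by_key[(snp, Stratum.AFF)].counts)
                + np.array(by_key[(snp, Stratum.UNAFF)].counts)
            )
            np.testing.assert_array_equal(all_counts, split)

    def test_null_calibration(self):
        """With f=0 and 1000 null female samples per rep, ~5% of exact
        HWE p-values fall below 0.05 (within the 99% binomial band)."""
        rng = np.random.default_rng(77)
        n_reps, n = 1000, 300
        rejections = 0
        for _ in range(n_reps):
            g = rng.choice(3, size=n, p=[0.49, 0.42, 0.09])
            p = hwe_exact_p(int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum()))
            rejections += p < 0.05
        rate = rejections / n_reps
        # exact test is conservative on discrete data: rate <= band top,
        # and not absurdly low
        assert rate <= 0.05 + 2.576 * math.sqrt(0.05 * 0.95 / n_reps)
        assert rate > 0.01


# ---------------------------------------------------------------------------
# Male heterozygotes and filters
# ---------------------------------------------------------------------------


class TestMaleHetScan:
    def test_clean_cohort_empty(self, rng):
        from conftest import random_cohort

        incidents, _ = male_het_scan(random_cohort(rng))
        assert incidents == []

    def test_injected_het_found_and_sanitized(self):
        cohort = make_cohort([[1, 0], [2, 2]], sexes=[1, 2])
        incidents, fixed = male_het_scan(cohort, sanitize=True)
        assert incidents == [("S0", "rs1")]
        assert fixed.genotypes[0, 0] == MISSING
        assert cohort.genotypes[0, 0] == 1  # input untouched
        again, _ = male_het_scan(fixed)
        assert again == []


class TestApplyQc:
    def test_study_missingness_fixture_fails_two_snps(self):
        """With the per-sex missingness pattern applied exactly, only the
        two high-female-missingness SNPs fail the <=2% criterion."""
        clean = tuple(
            spec.__class__(**{**spec.__dict__, "miss_f": 0.0, "miss_m": 0.0})
            for spec in DEFAULT_SNPS
        )
        cohort, _ = simulate_cohort(default_config(snps=clean), seed=4)
        fixture = apply_exact_missingness(cohort)
        _, report = apply_qc(
            fixture,
            QCThresholds(female_miss_max=0.02, diff_miss_p_min=None, maf_min=None, hwe_p_min=None),
        )
        assert sorted(report.excluded_snps) == ["rs11798018", "rs2073163"]

    def test_all_disabled_is_identity(self, rng):
        from conftest import random_cohort

        cohort = random_cohort(rng, n_min=6)
        filtered, report = apply_qc(
            cohort, QCThresholds(None, None, None, None, sanitize_male_hets=False)
        )
        assert filtered.snp_ids == cohort.snp_ids
        assert report.excluded_snps == []

    def test_monomorphic_snp_fails_maf(self):
        g = np.array([[0, 1], [0, 2], [0, 1], [0, 0]], dtype=np.int8)
        cohort = make_cohort(g, sexes=[2, 2, 2, 2], phenotypes=[1, 1, 2, 2])
        filtered, report = apply_qc(
            cohort, QCThresholds(female_miss_max=None, diff_miss_p_min=None, hwe_p_min=None)
        )
        assert report.excluded_snps == ["rs1"]
        assert filtered.snp_ids == ["rs2"]

    def test_hwe_requires_control_females(self):
        cohort = make_cohort([[1], [2]], sexes=[2, 2], phenotypes=[2, 2])
        with pytest.raises(ValueError, match="control females"):
            apply_qc(cohort, QCThresholds(None, None, None, hwe_p_min=1e-4))

    def test_decisions_recorded_per_criterion(self):
        cohort, _ = simulate_cohort(default_config(), seed=8)
        _, report = apply_qc(cohort)
        assert set(report.decisions["criterion"]) == {
            "female_missingness",
            "differential_missingness",
            "maf",
            "hwe_control_females",
        }
        assert len(report.decisions) == 4 * cohort.n_snps
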