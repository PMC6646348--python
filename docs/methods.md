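# Methods notes

This note records the statistical model behind `xchrom`, the defaults
and why they are what they are, what the synthetic data do and do not
emulate, and the numerical conventions a careful user should know.

## Scope and assumptions

Everything here targets biallelic SNPs in the non-pseudoautosomal region
of the X chromosome in a two-sex case-control or quantitative-trait
sample. Males are treated as strictly hemizygous: a male heterozygote
call is representable in the containers (so files can be read
faithfully) but is considered a calling error; `qc.male_het_scan`
reports and optionally blanks such calls, and the association layer
refuses dosage coding until they are gone. Pseudoautosomal markers,
multi-allelic sites, imputation and LD analysis are out of scope.

## Dosage coding and the XCI model

X-chromosome inactivation silences one X copy in most female cells. If
a locus undergoes XCI, an expressed male allele is dose-equivalent to a
female homozygote, so males are coded 0/2; if the locus escapes XCI,
both female copies are expressed and a male copy is half a female
homozygote's dose, so males are coded 0/1. Females are 0/1/2 A1 copies
either way, with a separate heterozygote indicator h for dominance.
The model is a per-locus analysis choice, not a data property: both
codings are first-class (`xci_code`, `export_dosage`) and the question
"which coding fits this gene in this tissue" is left to the analyst.

## The stratified score tests

The 1-df statistic treats sex as a stratifying variable. Within stratum
s the score for the additive dosage x against phenotype y is
U_s = Σ (y_i − ȳ_s) x_i with variance estimate
V_s = [Σ (y_i − ȳ_s)²] · Var_s(x) · n_s/(n_s − 1); the test is
(ΣU_s)²/(ΣV_s) referred to χ²₁. This V_s equals the exact variance of
U_s under within-stratum permutation of y, which is what makes the
chi-square calibration hold for binary and quantitative y alike and
what removes sex as a confounder: a mean shift between sexes (in y or
in allele frequency) is absorbed by the per-stratum centring.

Conventions worth stating:

- **(N−1) scaling.** With a single stratum and binary y the statistic
  equals (N−1)·r², the Mantel-extension form of the Cochran-Armitage
  trend test, not the N·r² textbook form. The two differ by N/(N−1) —
  irrelevant at study sizes, visible in unit tests — and the package
  uses the (N−1) form everywhere, including `trend_test_counts`, so the
  female-only reduction is an exact identity.
- **2-df test.** S2 scores the pair (x, h) jointly: T = Uᵀ V⁻ U with a
  Moore-Penrose generalized inverse and df = rank(V). Degenerate strata
  (males contribute nothing to h; a cohort may lack female hets
  entirely) reduce the rank instead of crashing; the reported df says
  what was actually tested.
- **Undefined statistics.** A constant phenotype or monomorphic dosage
  gives zero score variance; results carry `chi2=None` plus a reason
  string rather than NaN, and the Monte-Carlo harness counts and
  excludes such replicates (erroring if they exceed 10%).
- **Missing data** are dropped pairwise per (SNP, phenotype), so the
  reported N varies across cells exactly as in per-cell-complete
  association tables.
- **Quantitative traits** enter raw (no rank transform); the score test
  is location/scale invariant, which the suite checks.

## Exact tests

- **HWE (females only).** Two-sided exact test conditioning on allele
  counts, summing the probabilities of all heterozygote counts at most
  as probable as the observed one; computed by the standard ratio
  recurrence, no mid-p. Expected heterozygosity is reported as
  2p(1−p) without small-sample correction, which is what reproduces
  conventional QC report values from their printed counts.
- **Fisher tests** (differential missingness, sex-specific allele
  frequency, male allelic test) are two-sided by the point-probability
  rule — the sum over all tables with probability ≤ the observed one —
  via `scipy.stats.fisher_exact`. Allele counting weights females ×2
  and males ×1; odds ratios are oriented female-vs-male (QC) and
  case-vs-control (male allelic test).

## QC battery and thresholds

Per-SNP criteria, each independently disableable
(`QCThresholds(None, ...)`):

| criterion | default | rationale |
|---|---|---|
| female missingness | ≤ 0.02 | published X-QC guidance; male call rates are systematically worse, so the female rate is the informative one |
| differential missingness (M vs F) | exact p ≥ 10⁻⁷ | sex-differential call failure indicates intensity/clustering artefacts |
| minor-allele frequency | ≥ 0.01 | below this the exact tests and score tests are uninformative at panel sizes |
| exact HWE, control females | p ≥ 10⁻⁴ | cases may deviate through true association; males carry no HWE information |

HWE filtering is evaluated in control females only, but `hwe_table`
produces ALL/AFF/UNAFF strata for reporting. A SNP is removed iff at
least one enabled criterion fails; every decision is recorded with its
statistic in the `QCReport`.

## The synthetic cohort

The generator produces the statistical structure the pipeline needs to
be testable without controlled-access genotypes:

- female genotypes from a trinomial with an inbreeding-style
  disequilibrium coefficient f (het probability 2pq(1−f)) — a single
  parameter chosen because observed X-array female data show a roughly
  uniform heterozygote deficit; no mechanistic model of the deficit is
  attempted;
- male genotypes Bernoulli(p_m) mapped to {0, 2};
- missingness as independent Bernoulli per call within sex (real
  missingness is plate- and cluster-structured; no dependence is
  modelled);
- binary phenotypes either assigned by group counts independent of
  genotype (`null`) or drawn from a logistic model on the XCI-coded
  dosage and redrawn per sex until the configured case/control margins
  match (cap 10 000 draws). Margins are recruitment-fixed in the
  emulated design, so the logistic intercept — and any sex main effect
  γ — is centred within sex; γ therefore shifts which subjects are
  cases, not how many;
- quantitative traits as Gaussian noise around the dosage effect. Real
  metabolic traits (e.g. HOMA-IR) are right-skewed; emulating that is
  out of scope, so quantitative results validate calibration and
  invariances, not distributional robustness.

The default configuration (`default_config()`) is fixed to the study
design the package emulates: 915 children, 477 F / 438 M, controls
122 F / 136 M, cases 355 F / 302 M, eight SNPs with per-sex A1
frequencies between 0.26 and 0.46, per-sex missingness between 0.002
and 0.14, and f between 0.015 and 0.314 back-computed from the
reference female genotype counts as f = 1 − O(HET)/E(HET). The default
seed is 1729; all randomness flows from the single config seed through
one `numpy` Generator (no global state).

`apply_exact_missingness` is the deterministic counterpart for
bookkeeping tests: it blanks exactly ⌊rate·n_sex⌋ calls per sex per
SNP. Floor (not round) is used so a configured rate sitting exactly on
a filter boundary (e.g. 2% female missingness at n = 477) stays on the
passing side, matching the pass/fail pattern the rates encode.

## Monte-Carlo harness and problem sizes

`run_scenario` draws independent cohorts (per-replicate seeds spawned
from one generator), applies the chosen tests to a designated SNP, and
reports rejection rates with 99% binomial bands. Defaults: 2000
replicates, alpha grid {0.05, 0.01} — 2000 replicates put the 99% band
at 0.05 ± 0.013, tight enough to detect meaningful miscalibration while
a five-scenario sweep stays in the minutes range on one CPU. The test
suite uses 150–2000 replicates depending on how sharp the assertion is,
and the permutation cross-check of S1 uses 20 000 within-sex
permutations on a fixed n = 60 cohort, comparing the chi-square p to
the permutation **mid-p** (the statistic is discrete; its atom at the
observed value is ~0.02–0.1 at that n, and the chi-square approximation
tracks the mid-p).

The bundled scenarios encode the qualitative test-selection guidance:
balanced-design null (calibration), unbalanced design with sex-specific
frequencies (the naive pooled trend test inflates to ~0.20 empirical
type-I error at nominal 0.05 while S1 stays in band), additive effects
under XCI and escape codings, and a female-dominance-only effect where
S2 beats S1.

## File formats and numerical details

- PLINK 1 binary: SNP-major v1.00, 2-bit codes (00 hom-A1, 01 missing,
  10 het, 11 hom-A2), ceil(n/4) bytes per SNP, zero-bit padding;
  read/write is bit-exact round-trip. Chromosome X is accepted as "23"
  or "X" on input and emitted as 23. Missing phenotype accepts −9/0,
  emits −9. Genetic distance is carried as 0.
- The .ped/.map text dialect stores allele characters, not orientation,
  so A1 is re-derived on read as the minor allele (females ×2, males
  ×1; ties broken alphabetically; monomorphic columns get the "0"
  placeholder). Text round trips are therefore guaranteed only up to
  per-SNP allele orientation, and `cohorts_equivalent` defines that
  equivalence; binary round trips are strict.
- Long-format exports are pivoted order-invariantly (sorted sample/SNP
  axes); undetermined tokens become missing; conflicting duplicate
  records are an error, identical duplicates are not. Sample sex is
  taken from a supplied map, else inferred male iff any call is
  single-allele.
- Base-pair positions are carried verbatim; no genome-build liftover is
  attempted or recorded.
- Generalized-inverse rank decisions use `numpy.linalg.matrix_rank`
  defaults; exact-test tie comparisons use a 1 + 10⁻¹² relative slack,
  the convention that keeps equal-probability tables in the tail sum in
  floating point.

## Known limitations

- The score tests are asymptotic; at very small n or rare alleles the
  chi-square reference is approximate (the permutation machinery in the
  test suite shows how to get exact inference if needed).
- No sample-level QC (relatedness, heterozygosity-based sex checks,
  ancestry PCA) — the emulated workflow performs none.
- Sex-specific allele frequencies inflate the stratified tests' level
  too if the design is unbalanced *and* the effect is differential by
  sex in a way the coding does not capture; the harness only
  demonstrates the pooled-vs-stratified contrast.
- The 0/1 vs 0/2 male coding changes S1 only through the male stratum
  variance weighting, so XCI-vs-escape misspecification costs power,
  not level, under the null.
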