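# Methods

## Projected-distance regression

NPDR scores each variant by regressing phenotype discordance of
nearest-neighbor subject pairs on the variant's projected difference
("diff").  The neighborhood is built once, in the full variant space, and
shared by every per-SNP fit; covariates never enter the distance, only the
regressions.

**Diffs.** For dosage data (minor-allele counts 0/1/2) two diffs are
implemented: genotype mismatch (GM), the 0/1 indicator of different
genotypes, and allele mismatch (AM), |g_i − g_j|/2, which distinguishes
heterozygous from opposite-homozygous disagreement.  Both are symmetric and
bounded in [0, 1].  AM is the default.  Since only equality and absolute
differences of dosages are used, both diffs are invariant to which allele
is labeled "minor".  Covariate diffs are |c_i − c_j| scaled by the
covariate's observed range (raw absolute differences available via
`covar_scale="raw"`); a zero-range covariate is dropped with a warning.

**Distances and neighborhoods.** Inter-subject distance is the L_q norm of
the per-variant diffs (q = 1, Manhattan, by default).  The default
neighborhood is class-blind fixed-k with the adaptive size
k = ⌊0.154 (m − 1)⌋ (clamped to ≥ 1), ties at the k-th distance broken by
ascending subject index so runs are exactly reproducible.  A
hit-miss-balanced mode (k nearest same-class plus k nearest opposite-class
neighbors) is provided; the phrase "adaptive k for hits and misses" admits
both readings, and we default to the class-blind form while exposing the
other.

**Fitting.** For a binary phenotype the response over ordered neighbor
pairs (i, j) is the miss indicator 1[y_i ≠ y_j] and the model is a binomial
GLM with logit link; for a quantitative trait the response is |y_i − y_j|
and the model is OLS.  The test statistic is the Wald z (or t) for the diff
coefficient with the one-sided alternative β_a > 0.  Without covariates the
diff takes at most three values, so the likelihood depends on the data only
through six per-level counts; the per-SNP MLEs are computed by a batched
Newton iteration on these sufficient statistics (exactly equal to the dense
fit, verified in the tests against statsmodels and a likelihood grid
search).  With covariates a dense Newton/IRLS fit per SNP is used,
warm-started from the shared covariates-only fit.  Monomorphic-in-
neighborhood SNPs and separated fits are flagged (`constant_diff`,
`separation`) and reported as NA rather than aborting a run.  Bonferroni is
the default multiple-testing adjustment (Benjamini-Hochberg available).

**Ordered pairs and calibration.** The neighborhood is a set of *ordered*
pairs: when i and j are mutual neighbors, both (i, j) and (j, i) contribute
rows.  We keep this as the default because it is the method's published
formalism, and document the consequence: duplicated reciprocal rows inflate
Wald z by up to √2, and neighbor pairs share subjects, so inference is
approximate.  Empirically (null simulations in the test suite) the per-SNP
type-I error at nominal 0.05 stays within [0.03, 0.10], but the far tail
(p < 2.5e-3) is ~5x anti-conservative, enough that permuted-phenotype runs
produce an occasional Bonferroni discovery.  The `dedup_pairs` option
collapses to unordered unique pairs and restores far-tail calibration
(verified in the tests); users who need strict familywise control under
the null should prefer it.

## Population structure

PCs are computed from the variance-standardized relationship matrix:
dosages are standardized per SNP as z = (g − 2f)/√(2f(1−f)) with f the
sample allele frequency, and the top eigenvectors of ZZᵀ/p (equivalently
the left singular vectors of Z/√p) are returned with unit norm, explained
variance fractions, and a deterministic sign convention (largest-magnitude
loading positive).  PCs are intended to be computed on the post-QC,
LD-pruned variant set.  Their diffs enter NPDR as ordinary covariates.

Pair-level covariate adjustment has a structural limitation worth knowing:
|PC_i − PC_j| is near zero for *all* within-group pairs, so PC diffs can
only absorb confounding that flows through cross-group neighbor pairs.
Confounding that acts by pooling groups with different within-group miss
rates and diff distributions (a Simpson-type pattern) is invisible to any
pair-difference covariate.  The confound fixture in the test suite is
constructed accordingly (mirrored allele frequencies and prevalences, so
the confounding is purely cross-group), and the adjustment criterion is
asserted on medians across five replicates because single runs carry
clustered-pair noise.

## QC filters

Variant filters follow GWAS practice: MAF ≥ 0.01 (folded frequency from
dosage sums); Hardy-Weinberg 1-df chi-square goodness-of-fit at the
observed allele frequency, applied in controls (p > 0.01) and cases
(p > 1e-4) separately — the loose thresholds make the chi-square
approximation adequate, an exact test is a possible extension; greedy
left-to-right LD pruning that drops the later (or optionally the
lower-MAF) SNP of any retained pair with |r| above 0.5 ("correlation"
read as |r|, with r² exposed as an option); and an optional univariate
prefilter keeping the top-N SNPs by single-variant association
(unadjusted by default; the prefilter is a memory concession, not part of
the method).  Zero-variance SNPs have LD correlation defined as 0 and are
left to the MAF filter.  All filters are idempotent.

## Simulator

Disease models are penetrance tables f(g) with genotype frequencies at
Hardy-Weinberg proportions for the model MAF; heritability is measured on
the penetrance scale, h² = Σ_g p(g)(f(g) − K)²/(K(1−K)) with prevalence
K = Σ_g p(g) f(g).  Default parameters are the benchmark conditions:
h² = 0.4 (0.05 for the low-heritability pair design), MAF 0.2, 800/800
cases/controls (960/640 imbalanced), 20 or 10,000 variants, background MAF
0.2.  K defaults to 0.3; any K compatible with f ∈ [0, 1] is accepted.

**Pure-epistasis tables** are built by rejection: a random 3×3 table is
double-centered under HWE weights (which zeroes both single-locus marginal
penetrances exactly), scaled to the target variance, and rejected unless
all nine entries are valid probabilities.  Realized h² equals the target to
machine precision and is re-verified by cell enumeration in the tests.  At
the default (h²=0.4, MAF 0.2, K=0.3) about 0.4% of proposals are valid.

**Model selection.** Equal-h² tables differ enormously in how detectable
they are to nearest-neighbor methods (observed functional-SNP ranks from
top-10 to worse-than-random at p = 10,000 across random tables).  The
benchmark generator this module emulates ranks candidate models by an
ease-of-detection measure and keeps the top one; we do the same: the
registered designs draw 50 valid candidate tables and keep the table
maximizing `nearest_neighbor_signal` — the population slope of diff on
pair discordance among pairs that agree at the partner locus, i.e. exactly
the conditional signal a tight neighborhood exposes.  (Unconditioned, that
slope is identically zero for any pure-epistasis table.)  The low-level
constructor defaults to no selection.

**Sampling.** Case-control data are drawn retrospectively: subjects are
generated from the population model (functional genotypes at HWE, disease
via Bernoulli(f(g))) and kept until the case and control quotas fill.
Background variants are i.i.d. Binomial(2, MAF) independent of status, and
all columns are placed in random order with the functional identities
recorded in a truth object.  Continuous outcomes are y = (f(g) − K) + ε
with ε Gaussian and variance set so the genetic fraction equals h²; the
table's overall scale cancels against the noise calibration.

**Main effects.** The two-locus main-effect design is additive:
f(g) = K + Σ_l c_l e_l(g_l) with zero-mean per-locus deviations each
scaled to h²/L, so each locus's marginal table carries exactly h²/L
(verified by enumeration).  For four loci the equal-split additive
construction has *no* valid solution at the benchmark settings (the
deviation budget forced by f ∈ [0, 1] under HWE weights (0.64, 0.32, 0.04)
cannot reach h²/4 per locus for any K), so the four-locus design uses
sample heterogeneity instead — each subject's disease status is governed by
one locus's single-locus model at full h², giving the 25:25:25:25
influence split; the two-pair interaction design uses the same mechanism
with two independent pure-epistasis pairs at assignment probability 0.5.

**What the generator does not emulate:** linkage disequilibrium among
background variants, allele-frequency spectra, covariate or ancestry
structure (the two-subpopulation confound fixture lives in the test suite),
and byte-level compatibility with any external tool.  Passing tests on
these data show the method's behavior under idealized independence, not
performance on real LD-structured genomes.

## Baselines and the epistasis network

The univariate baseline is per-SNP additive-coding logistic/linear
regression with two-sided Wald p (fitted from the 2×3 sufficient table for
the binary case; verified against statsmodels).  The random-forest baseline
(500 trees default, seeded) ranks by impurity importance by default —
permutation importance is available but is the slow path at p = 10,000 —
and is used for the high-dimensional contrast: at p = 10,000 its
functional-SNP ranks are consistent with the random expectation p/2 while
NPDR keeps the pair in the top tail.

The network stage tests all unordered pairs of a selected SNP set (top-K
NPDR hits by default) with the logistic model y ~ g1 + g2 + g1·g2 plus
covariate main effects, adjusts the product-term p across exactly the
tested pairs (Benjamini-Hochberg default — step-up adjustment matches the
tied-smallest-adjusted-p pattern such tables show; Bonferroni available),
keeps edges below adjusted p 1e-6, and weights them by −log₁₀(adjusted p).
Failed fits (separation, collinearity) are NA and excluded from the test
count.  Hub extraction and degree tables come from the networkx graph.

## Numerical choices and problem sizes

Logistic fits run Newton/IRLS to score tolerance 1e-10 with step-halving
(dense) or a light trust region (batched); non-converged or |β| > 30 fits
are flagged as separated.  Distances use float32 BLAS-friendly scipy
kernels; exact nearest-neighbor search only (the design envelope is
m ≤ ~10⁴ subjects).  Neighbor ties and all rankings break deterministically
(by index or SNP ID), and every stochastic stage takes an explicit seed;
one pipeline seed expands into per-stage seeds via `SeedSequence`.

Replicate counts in the shipped tests and acceptance script (10 replicates
for the p=20 power check, 5–8 for the p=10,000 contrast, 200 small
replicates for null calibration) are the package's choice of problem sizes:
large enough for stable medians/means of the quantities asserted, small
enough to run a full suite interactively on one CPU (~15 minutes).

## Known limitations

* Wald inference on overlapping ordered pairs is approximate: near-nominal
  at α = 0.05, anti-conservative in the far tail (see above; `dedup_pairs`
  mitigates).  The published formalism is kept as the default.
* PC-diff covariate adjustment cannot absorb within-group (Simpson-type)
  confounding, only cross-group confounding.
* The RF baseline's "permutation p-value" variant is approximated by
  importance ranking; no permutation-null p is computed for RF.
* The simulator's detectability selection emulates the benchmark's
  model-selection step; with selection disabled, power at p = 10,000 varies
  strongly across random tables of equal h².
* VCF/BED parsing, genotype calling, LD-aware windowed pruning, mixed
  models and 3-way interactions are out of scope.
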