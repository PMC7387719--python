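# npdr — nearest-neighbor projected-distance regression for GWAS

Single-variant association tests miss genetic effects that only appear
through interactions (epistasis), and the standard machine-learning
work-arounds either lose power as the number of variants grows (random
forests) or provide no statistical significance machinery at all
(Relief-family feature selection).  **NPDR** closes that gap: it keeps the
nearest-neighbor construction that makes Relief-based methods sensitive to
interactions, but turns the scoring step into a generalized linear model so
that every variant gets a regression coefficient, a p-value, a
multiple-testing adjustment — and, crucially, covariate adjustment for
population structure.

This package is a complete Python implementation for GWAS-scale dosage
data, aimed at statistical geneticists and ML-in-genomics researchers: the
core projected-distance regression (binary and quantitative traits, with
principal-component covariates), the GWAS filtering stack (MAF, HWE, LD
pruning, univariate prefilter), PCA on the variance-standardized
relationship matrix, a penetrance-table simulator for epistatic and
main-effect benchmark designs, univariate and random-forest baselines, and
an epistasis-network stage built from pairwise logistic interaction tests.

## The model

Subject *i* is a point in the space of *p* variants coded as minor-allele
dosage (0/1/2).  Let N_i be the k nearest neighbors of *i* under the
Manhattan metric on per-variant *projected differences* ("diffs"), with the
adaptive neighborhood size k = ⌊0.154 (m − 1)⌋.  Two diffs are available
per SNP *a*:

* genotype mismatch, d_ij(a) = 1[g_ia ≠ g_ja]
* allele mismatch, d_ij(a) = |g_ia − g_ja| / 2 ∈ {0, 0.5, 1}

For every ordered neighbor pair (i, j) and every SNP *a*, NPDR fits

    logit P(miss_ij) = β₀ + β_a d_ij(a) + β_covsᵀ d_ij(covs)      (case/control)
    |y_i − y_j|      = β₀ + β_a d_ij(a) + β_covsᵀ d_ij(covs) + ε   (quantitative)

where miss_ij = 1 if i and j are in opposite phenotype classes, and
d_ij(covs) are range-scaled absolute covariate differences (e.g. of the top
10 PCs of the variance-standardized relationship matrix).  The importance
statistic is β̂_a with the one-sided alternative β_a > 0 — informative SNPs
show larger diffs across phenotypically discordant neighbor pairs — and
e^β_a is the change in odds of neighbor discordance per unit diff.
Bonferroni (default) or Benjamini-Hochberg adjustment is applied across
SNPs.  Because the diff of a dosage pair takes at most three values, every
per-SNP GLM is fitted exactly from six sufficient-statistic counts, which
is what makes 10,000-variant runs take about a minute.

## Worked example

```python
import npdr

# a pure epistatic pair: h2 = 0.4, MAF 0.2, 800 cases / 800 controls,
# 20 variants; neither functional SNP has any marginal effect
G, y, truth = npdr.simulate_design("interact-pair", seed=3, h2=0.4)
print(truth.functional_snps)          # ['M1', 'M2']

result = npdr.run_npdr(G, y)          # AM diff, adaptive k, Bonferroni
print(result.top(4)[["snp", "beta", "p_one_sided", "p_adjusted", "rank"]])
```

```
['M1', 'M2']
snp      beta  p_one_sided  p_adjusted  rank
 M1  0.831762     0.000000         0.0     1
 M2  0.872397     0.000000         0.0     2
N18 -0.014417     0.880766         1.0     3
 N3 -0.043815     0.999880         1.0     4
```

Both interacting variants are ranked 1–2 with Bonferroni-adjusted p ≈ 0,
while every background variant (N…) is flat — a univariate test on the same
data finds nothing (adjusted p 0.52 and 1.0 for M1/M2), because each
functional SNP is marginally null.  The positive β̂ ≈ 0.83 means each
0.5-step of allele mismatch multiplies the odds that two neighbors are
phenotypically discordant by e^0.42 ≈ 1.52.  Run
`python examples/01_detect_epistasis.py` to reproduce.

The same API drives the rest of the pipeline: `apply_qc` (MAF/HWE/LD/top-N
filters), `genotype_pcs` (PC covariates), `univariate_assoc` /
`rf_importance` (baselines), and `build_network` (pairwise logistic
interaction tests over the top NPDR hits, edges at adjusted p < 1e-6,
weights −log₁₀ adjusted p).  Short narrative scripts for each capability
live in `examples/`.

A thin CLI mirrors the library:

```bash
npdr simulate --design interact-pair --h2 0.4 --seed 42 --out-prefix sim1
npdr run sim1.raw --out results.tsv
npdr network sim1.raw --top-k 10 --alpha 1e-6 --out edges.tsv
```

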