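"""Replicate benchmark: NPDR vs univariate regression vs random forest.

Runs a few replicates of the two-SNP main-effect design; all methods find
main effects, which is the sanity half of the benchmark (the epistasis
half, where univariate fails, is example 01).
"""

from npdr.pipeline import run_benchmark

per_rep, summary = run_benchmark("main-pair", n_replicates=3,
                                 methods=("npdr", "univariate", "rf"),
                                 seed=0, n_cases=400, n_controls=400,
                                 rf_trees=200)
print(summary.to_string(index=False))
print("\nmean_rank is over the functional SNPs (1 is best of 20); "
      "detection_rate is the fraction with Bonferroni-adjusted p < 0.05 "
      "(rank-only for rf).")
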