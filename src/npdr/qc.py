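"""GWAS variant filtering: MAF, Hardy-Weinberg, LD pruning, univariate prefilter.

Defaults follow common GWAS practice for case-control data: MAF >= 0.01,
HWE p > 0.01 in controls and > 1e-4 in cases, greedy LD pruning at
|r| > 0.5, and an optional univariate-association prefilter to a top-N set
for methods whose memory scales with the variant count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import GenotypeMatrix, PhenotypeVector

__all__ = [
    "QcConfig",
    "minor_allele_freq",
    "hwe_test",
    "hwe_counts",
    "ld_prune",
    "univariate_prefilter",
    "apply_qc",
]


@dataclass
class QcConfig:
    maf_min: float = 0.01
    hwe_p_controls_min: float = 0.01
    hwe_p_cases_min: float = 1e-4
    ld_r_threshold: float = 0.5
    ld_stat: str = "r"  # "r" -> |r|, "r2" -> r^2 against the threshold
    prefilter_top_n: int | None = 10_000

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        for t in (self.hwe_p_controls_min, self.hwe_p_cases_min):
            if not 0 < t <= 1:
                raise ValueError("HWE thresholds must be in (0, 1]")
        if self.prefilter_top_n is not None and self.prefilter_top_n < 1:
            raise ValueError("prefilter_top_n must be >= 1")


def minor_allele_freq(dosage_column, missing_mask=None) -> float:
    """min(f, 1-f) with f = (sum of dosages) / (2 * non-missing count)."""
    g = np.asarray(dosage_column, dtype=float)
    if missing_mask is not None:
        g = g[~np.asarray(missing_mask, dtype=bool)]
    if g.size == 0:
        raise ValueError("all genotypes missing; MAF undefined")
    f = g.sum() / (2.0 * g.size)
    return float(min(f, 1.0 - f))


def hwe_counts(dosage_column) -> tuple[int, int, int]:
    g = np.asarray(dosage_column)
    return (int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit p against Hardy-Weinberg proportions.

    Expected counts use the observed allele frequency.  Monomorphic input
    (zero expected heterozygotes) returns p = 1.
    """
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    f = (n_Aa + 2 * n_aa) / (2.0 * n)
    if f <= 0.0 or f >= 1.0:
        return 1.0  # monomorphic
    expected = n * np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def ld_prune(G: GenotypeMatrix, r_threshold: float = 0.5, stat: str = "r",
             drop: str = "later") -> GenotypeMatrix:
    """Greedy left-to-right LD pruning on dosage correlations.

    When a candidate SNP correlates with an already-retained SNP above the
    threshold, one of the two is dropped: the later (scan order, default) or
    the lower-MAF one.  Zero-variance SNPs have correlation defined as 0.
    No retained pair exceeds the threshold on exit.
    """
    if G.n_snps < 2:
        raise ValueError("need at least two SNPs to prune")
    X = G.dosage.astype(float)
    sd = X.std(axis=0)
    Xc = X - X.mean(axis=0)
    mafs = np.array([minor_allele_freq(X[:, j]) for j in range(G.n_snps)])
    retained: list[int] = []
    for j in range(G.n_snps):
        if sd[j] == 0:
            retained.append(j)  # r defined as 0; MAF filter handles these
            continue
        while True:
            poly = [i for i in retained if sd[i] > 0]
            if not poly:
                retained.append(j)
                break
            r = (Xc[:, poly].T @ Xc[:, j]) / (len(X) * sd[poly] * sd[j])
            val = r**2 if stat == "r2" else np.abs(r)
            hits = np.flatnonzero(val > r_threshold)
            if hits.size == 0:
                retained.append(j)
                break
            if drop == "later":
                break  # drop j
            # drop the lower-MAF member; if that is a retained SNP, remove it
            # and re-test j against the remainder
            worst = poly[hits[np.argmin(mafs[[poly[h] for h in hits]])]]
            if mafs[j] <= mafs[worst]:
                break  # j is the lower-MAF one
            retained.remove(worst)
    return G.subset_snps(retained)


def univariate_prefilter(G: GenotypeMatrix, y: PhenotypeVector,
                         top_n: int = 10_000) -> GenotypeMatrix:
    """Keep the top_n SNPs by univariate additive-model association p.

    Ties at the cutoff break by SNP ID; original column order is preserved
    among the retained set.
    """
    from .baselines import univariate_assoc

    if top_n >= G.n_snps:
        if top_n > G.n_snps:
            warnings.warn(f"top_n={top_n} exceeds p={G.n_snps}; keeping all SNPs")
        return G.subset_snps(np.arange(G.n_snps))
    res = univariate_assoc(G, y).table
    res = res.assign(_order=np.arange(len(res)))
    chosen = res.sort_values(["p", "snp"], kind="stable", na_position="last").head(top_n)
    idx = np.sort(chosen["_order"].to_numpy())
    return G.subset_snps(idx)


def apply_qc(G: GenotypeMatrix, y: PhenotypeVector | None = None,
             config: QcConfig | None = None) -> tuple[GenotypeMatrix, dict]:
    """MAF -> HWE (controls, then cases) -> LD prune -> univariate prefilter.

    HWE and the prefilter need a binary / paired phenotype respectively and
    are skipped otherwise.  Returns the filtered matrix and a report of
    counts removed per stage.
    """
    config = config or QcConfig()
    report: dict = {"p_in": G.n_snps}
    X = G.dosage

    mafs = np.array([minor_allele_freq(X[:, j],
                                       None if G.missing_mask is None else G.missing_mask[:, j])
                     for j in range(G.n_snps)])
    keep = mafs >= config.maf_min
    report["removed_maf"] = int((~keep).sum())

    if y is not None and y.kind == "binary":
        controls = y.values == 0
        cases = ~controls
        for label, rows, thresh in (("controls", controls, config.hwe_p_controls_min),
                                    ("cases", cases, config.hwe_p_cases_min)):
            p_hwe = np.array([hwe_test(*hwe_counts(X[rows, j]))
                              for j in range(G.n_snps)])
            newly = keep & ~(p_hwe > thresh)
            report[f"removed_hwe_{label}"] = int(newly.sum())
            keep &= p_hwe > thresh
    G2 = G.subset_snps(np.flatnonzero(keep))

    if G2.n_snps >= 2:
        G3 = ld_prune(G2, config.ld_r_threshold, config.ld_stat)
    else:
        G3 = G2
    report["removed_ld"] = G2.n_snps - G3.n_snps

    if config.prefilter_top_n is not None and y is not None:
        G4 = univariate_prefilter(G3, y, config.prefilter_top_n)
    else:
        G4 = G3
    report["removed_prefilter"] = G3.n_snps - G4.n_snps
    report["p_out"] = G4.n_snps
    return G4, report
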