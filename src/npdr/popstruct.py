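"""Principal components from the variance-standardized relationship matrix.

Genotypes are standardized per SNP as z = (g - 2f) / sqrt(2 f (1 - f)) with
f the sample allele frequency; the relationship matrix is Z Z' / p and its
top eigenvectors (unit norm, deterministic sign) serve as covariates for
population-structure adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import CovariateTable, GenotypeMatrix

__all__ = ["PcScores", "standardize_genotypes", "compute_pcs"]


@dataclass
class PcScores:
    samples: list[str]
    scores: np.ndarray  # m x n_pcs, unit-norm columns
    explained: np.ndarray  # variance fractions, non-increasing

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]

    def to_covariates(self) -> CovariateTable:
        names = [f"PC{i + 1}" for i in range(self.n_pcs)]
        return CovariateTable(names=names, values=self.scores, samples=self.samples)


def standardize_genotypes(G: GenotypeMatrix) -> np.ndarray:
    """Column-standardize dosages by HWE mean 2f and variance 2f(1-f)."""
    if G.has_missing:
        raise ValueError("missing genotypes; impute before standardization")
    X = G.dosage.astype(float)
    f = X.mean(axis=0) / 2.0
    mono = (f <= 0) | (f >= 1)
    if mono.any():
        bad = [G.snps[j] for j in np.flatnonzero(mono)[:5]]
        raise ValueError(
            f"monomorphic SNPs present (e.g. {bad}); apply a MAF filter first"
        )
    return (X - 2 * f) / np.sqrt(2 * f * (1 - f))


def compute_pcs(Z: np.ndarray, n_pcs: int = 10) -> PcScores:
    """Top principal components of the relationship matrix Z Z' / p.

    Scores are unit-norm eigenvectors with a deterministic sign convention
    (the largest-magnitude loading of each PC is positive).  ``n_pcs``
    beyond the matrix rank is truncated with a warning.
    """
    Z = np.asarray(Z, dtype=float)
    m, p = Z.shape
    if n_pcs > min(m, p):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(m, p)={min(m, p)}")
    # SVD of Z/sqrt(p): left singular vectors are the eigenvectors of ZZ'/p
    U, s, _ = np.linalg.svd(Z / np.sqrt(p), full_matrices=False)
    eigvals = s**2
    rank = int((eigvals > eigvals[0] * 1e-12).sum()) if eigvals.size else 0
    if n_pcs > rank:
        warnings.warn(f"requested {n_pcs} PCs but rank is {rank}; truncating")
        n_pcs = max(rank, 1)
    scores = U[:, :n_pcs].copy()
    for j in range(n_pcs):
        lead = np.argmax(np.abs(scores[:, j]))
        if scores[lead, j] < 0:
            scores[:, j] = -scores[:, j]
    total = eigvals.sum()
    explained = eigvals[:n_pcs] / total if total > 0 else np.zeros(n_pcs)
    return PcScores(samples=None, scores=scores, explained=explained)


def genotype_pcs(G: GenotypeMatrix, n_pcs: int = 10) -> PcScores:
    """Convenience wrapper: standardize then extract PCs, carrying sample IDs."""
    pcs = compute_pcs(standardize_genotypes(G), n_pcs)
    pcs.samples = list(G.samples)
    return pcs
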