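"""Projected diff functions, multivariate distances and neighborhoods.

The projected difference ("diff") of two individuals on one SNP is the
regression predictor of the projected-distance model.  Two diffs are
provided for dosage data:

* genotype mismatch (GM): 0 for identical genotypes, 1 otherwise;
* allele mismatch (AM): half the absolute dosage difference, i.e.
  0, 0.5 or 1 as the pair shares 2, 1 or 0 alleles at the locus.

Multivariate distances are L_q metrics over per-attribute diffs
(q = 1, Manhattan, by default), and neighborhoods are fixed-k nearest
neighbors with an adaptive size rule k = floor(0.154 (m - 1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import GenotypeMatrix, PhenotypeVector

__all__ = [
    "diff_gm",
    "diff_am",
    "diff_numeric",
    "pairwise_distance",
    "adaptive_k",
    "find_neighbors",
    "NeighborPairSet",
    "ADAPTIVE_K_FRACTION",
]

#: Neighborhood-size fraction of (m - 1); balances main-effect and
#: interaction detection for fixed-k Relief-style neighborhoods.
ADAPTIVE_K_FRACTION = 0.154


def _check_dosage(*gs) -> list[np.ndarray]:
    out = []
    for g in gs:
        g = np.asarray(g, dtype=float)
        if np.isnan(g).any():
            raise ValueError("missing dosage in diff; impute genotypes first")
        if not np.isin(g, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage values must be in {0,1,2}")
        out.append(g)
    return out


def diff_gm(g_i, g_j):
    """Genotype-mismatch diff: 0 if genotypes are identical, else 1."""
    g_i, g_j = _check_dosage(g_i, g_j)
    out = (g_i != g_j).astype(float)
    return float(out) if out.ndim == 0 else out


def diff_am(g_i, g_j):
    """Allele-mismatch diff: |g_i - g_j| / 2, i.e. 0, 0.5 or 1."""
    g_i, g_j = _check_dosage(g_i, g_j)
    out = np.abs(g_i - g_j) / 2.0
    return float(out) if out.ndim == 0 else out


def diff_numeric(x_i, x_j, value_range: float):
    """Range-scaled numeric diff |x_i - x_j| / range, used for covariates."""
    if value_range <= 0:
        raise ValueError("value_range must be positive")
    return np.abs(np.asarray(x_i, dtype=float) - np.asarray(x_j, dtype=float)) / value_range


def pairwise_distance(G, metric: str = "am", q: float = 1.0) -> np.ndarray:
    """m x m distance matrix D_ij = (sum_a |d_ij(a)|^q)^(1/q).

    ``metric`` selects the per-SNP diff (``am`` or ``gm``); ``q=1`` is the
    Manhattan metric used by default.
    """
    if q < 1:
        raise ValueError("metric order q must be >= 1")
    X = G.dosage if isinstance(G, GenotypeMatrix) else np.asarray(G)
    if isinstance(G, GenotypeMatrix) and G.has_missing:
        raise ValueError("genotype matrix has missing values; impute first")
    if X.shape[0] < 2:
        raise ValueError("need at least two instances")
    X = X.astype(np.float32)
    if metric == "am":
        # |g_i - g_j|/2 per SNP, so the L_q distance is Minkowski on X/2
        if q == 1:
            D = squareform(pdist(X / 2.0, metric="cityblock"))
        elif q == 2:
            D = squareform(pdist(X / 2.0, metric="euclidean"))
        else:
            D = squareform(pdist(X / 2.0, metric="minkowski", p=q))
    elif metric == "gm":
        # diffs are 0/1, so sum of d^q is the mismatch count for any q
        counts = squareform(pdist(X, metric="hamming")) * X.shape[1]
        D = counts ** (1.0 / q)
    else:
        raise ValueError(f"unknown diff metric {metric!r}")
    return D.astype(np.float64)


def adaptive_k(m: int) -> int:
    """Adaptive neighborhood size k = floor(0.154 (m - 1)), clamped to >= 1."""
    if m < 2:
        raise ValueError("need at least two instances")
    return max(1, int(np.floor(ADAPTIVE_K_FRACTION * (m - 1))))


@dataclass
class NeighborPairSet:
    """Ordered neighbor pairs (i, j) with j in N_i.

    ``i_idx``/``j_idx`` are parallel arrays over all ordered pairs; ``k_per``
    gives each instance's neighbor count k_i.  ``meta`` records the metric
    and neighborhood rule used, for provenance.
    """

    i_idx: np.ndarray
    j_idx: np.ndarray
    k_per: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.i_idx = np.asarray(self.i_idx, dtype=np.intp)
        self.j_idx = np.asarray(self.j_idx, dtype=np.intp)
        if (self.i_idx == self.j_idx).any():
            raise ValueError("self-pairs are not allowed in a neighborhood")
        if (np.asarray(self.k_per) <= 0).any():
            raise ValueError("every instance must have at least one neighbor")

    @property
    def n_pairs(self) -> int:
        return len(self.i_idx)

    def dedup(self) -> "NeighborPairSet":
        """Collapse (i,j)/(j,i) duplicates to unique unordered pairs."""
        lo = np.minimum(self.i_idx, self.j_idx)
        hi = np.maximum(self.i_idx, self.j_idx)
        keys = np.unique(lo * (hi.max() + 1) + hi)
        nlo, nhi = keys // (hi.max() + 1), keys % (hi.max() + 1)
        k_per = np.bincount(nlo, minlength=len(self.k_per))
        k_per = np.maximum(k_per, 1)  # counts are bookkeeping only after dedup
        return NeighborPairSet(nlo, nhi, k_per, {**self.meta, "dedup": True})


def find_neighbors(distances: np.ndarray, k: int, mode: str = "class-blind",
                   y: PhenotypeVector | None = None) -> NeighborPairSet:
    """Build the ordered-pair neighborhood from a distance matrix.

    ``class-blind`` takes each instance's k nearest others; ties at the k-th
    distance break by ascending instance index.  ``hit-miss-balanced`` takes
    the k nearest same-class plus k nearest opposite-class instances and
    requires a binary phenotype; a class with <= k members reduces k to the
    class size minus one (same class) with a warning.
    """
    D = np.asarray(distances, dtype=float)
    m = D.shape[0]
    if D.shape != (m, m):
        raise ValueError("distance matrix must be square")
    if not 1 <= k < m:
        raise ValueError(f"k must be in [1, m-1], got {k} for m={m}")

    if mode == "class-blind":
        Dw = D.copy()
        np.fill_diagonal(Dw, np.inf)
        order = np.argsort(Dw, axis=1, kind="stable")[:, :k]
        i_idx = np.repeat(np.arange(m), k)
        j_idx = order.ravel()
        return NeighborPairSet(i_idx, j_idx, np.full(m, k),
                               {"mode": mode, "k": k})
    if mode == "hit-miss-balanced":
        if y is None or y.kind != "binary":
            raise ValueError("hit-miss-balanced mode requires a binary phenotype")
        yv = y.values.astype(int)
        i_list, j_list, k_per = [], [], np.zeros(m, dtype=int)
        for cls in (0, 1):
            members = np.flatnonzero(yv == cls)
            others = np.flatnonzero(yv != cls)
            k_same = min(k, len(members) - 1)
            k_opp = min(k, len(others))
            if k_same < k or k_opp < k:
                import warnings

                warnings.warn(
                    f"class {cls}: reducing neighbor count to class size "
                    f"(k_same={k_same}, k_opp={k_opp})"
                )
            for i in members:
                for pool, kk in ((members, k_same), (others, k_opp)):
                    cand = pool[pool != i]
                    order = cand[np.argsort(D[i, cand], kind="stable")[:kk]]
                    i_list.append(np.full(len(order), i))
                    j_list.append(order)
                    k_per[i] += len(order)
        return NeighborPairSet(np.concatenate(i_list), np.concatenate(j_list),
                               k_per, {"mode": mode, "k": k})
    raise ValueError(f"unknown neighborhood mode {mode!r}")
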