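"""Nearest-neighbor projected-distance regression (NPDR).

For each SNP *a*, a GLM is fitted over the ordered neighbor pairs
(i, j) in the neighborhood set:

* binary phenotype: ``logit P(miss_ij) = b0 + b_a d_ij(a) [+ b_covs' d_ij(covs)]``
  where ``miss_ij = 1`` iff i and j are in opposite classes;
* continuous phenotype: ``|y_i - y_j| = b0 + b_a d_ij(a) [+ ...] + e_ij``.

The importance statistic is ``b_a`` with the one-sided alternative
``b_a > 0``: an informative SNP shows larger projected diffs among
phenotypically discordant neighbor pairs.  Inference is Wald-based and,
because neighbor pairs share instances, approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _glm
from .io import CovariateTable, GenotypeMatrix, PhenotypeVector
from .neighbors import (NeighborPairSet, adaptive_k, find_neighbors,
                        pairwise_distance)

__all__ = [
    "ProjectedDesign",
    "NpdrResult",
    "build_design",
    "fit_binary",
    "fit_continuous",
    "run_npdr",
    "adjust_pvalues",
]

_SNP_CHUNK = 512  # SNP columns per pass when tallying pair diffs


@dataclass
class ProjectedDesign:
    """Per-pair regression frame for one SNP: response, diff, covariate diffs."""

    response: np.ndarray
    attr_diff: np.ndarray
    covar_diffs: np.ndarray | None = None
    covar_names: list[str] = field(default_factory=list)
    binary: bool = True

    @property
    def n_pairs(self) -> int:
        return len(self.response)

    def design_matrix(self) -> np.ndarray:
        cols = [np.ones(self.n_pairs), self.attr_diff]
        if self.covar_diffs is not None and self.covar_diffs.shape[1]:
            cols.append(self.covar_diffs)
        return np.column_stack(cols)


@dataclass
class NpdrResult:
    """Per-SNP NPDR fits: beta, se, test statistic, one-sided p, adjusted p, rank."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.sort_values("rank").head(n)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SingleFit:
    beta: float
    se: float
    stat: float
    p_one_sided: float
    flag: str = "ok"  # ok | constant_diff | separation | not_converged


def _diff_values(g_i, g_j, metric: str) -> np.ndarray:
    d = np.abs(g_i.astype(np.int16) - g_j.astype(np.int16))
    if metric == "am":
        return d / 2.0
    if metric == "gm":
        return (d > 0).astype(float)
    raise ValueError(f"unknown diff metric {metric!r}")


def _covariate_diffs(covars: CovariateTable, i_idx, j_idx,
                     scale: str = "range") -> tuple[np.ndarray, list[str]]:
    """Pairwise numeric diffs |c_i - c_j|, range-scaled by default.

    Zero-range covariates carry no information and are dropped with a warning.
    """
    vals = covars.values
    rng = vals.max(axis=0) - vals.min(axis=0)
    keep = rng > 0
    if not keep.all():
        import warnings

        dropped = [n for n, k in zip(covars.names, keep) if not k]
        warnings.warn(f"dropping constant covariates: {dropped}")
    vals = vals[:, keep]
    rng = rng[keep]
    diffs = np.abs(vals[i_idx] - vals[j_idx])
    if scale == "range":
        diffs = diffs / rng
    elif scale != "raw":
        raise ValueError(f"unknown covariate scaling {scale!r}")
    return diffs, [n for n, k in zip(covars.names, keep) if k]


def build_design(pairs: NeighborPairSet, G: GenotypeMatrix, a, y: PhenotypeVector,
                 covars: CovariateTable | None = None, metric: str = "am",
                 covar_scale: str = "range") -> ProjectedDesign:
    """One regression row per ordered neighbor pair for SNP ``a``.

    ``a`` is a SNP ID or column index.  The binary response is the miss
    indicator 1[y_i != y_j]; the continuous response is |y_i - y_j|.
    """
    col = G.snps.index(a) if isinstance(a, str) else int(a)
    g = G.dosage[:, col]
    i_idx, j_idx = pairs.i_idx, pairs.j_idx
    if y.kind == "binary":
        response = (y.values[i_idx] != y.values[j_idx]).astype(float)
    else:
        response = np.abs(y.values[i_idx] - y.values[j_idx])
    attr = _diff_values(g[i_idx], g[j_idx], metric)
    cov_d, cov_names = (None, [])
    if covars is not None:
        cov_d, cov_names = _covariate_diffs(covars, i_idx, j_idx, covar_scale)
    return ProjectedDesign(response=response, attr_diff=attr, covar_diffs=cov_d,
                           covar_names=cov_names, binary=(y.kind == "binary"))


def fit_binary(design: ProjectedDesign, start: np.ndarray | None = None) -> SingleFit:
    """Logistic MLE of the miss indicator on the projected diff (Wald, one-sided)."""
    if np.ptp(design.attr_diff) == 0:
        return SingleFit(np.nan, np.nan, np.nan, np.nan, "constant_diff")
    u = np.unique(design.response)
    if len(u) < 2:
        return SingleFit(np.nan, np.nan, np.nan, np.nan, "constant_diff")
    X = design.design_matrix()
    fit = _glm.irls_logistic(X, design.response, start=start)
    if fit.separated or fit.cov is None:
        flag = "separation" if fit.separated else "not_converged"
        return SingleFit(np.nan, np.nan, np.nan, np.nan, flag)
    beta = fit.beta[1]
    se = float(np.sqrt(fit.cov[1, 1]))
    z = beta / se
    return SingleFit(float(beta), se, float(z), float(stats.norm.sf(z)))


def fit_continuous(design: ProjectedDesign) -> SingleFit:
    """OLS of |y_i - y_j| on the projected diff; one-sided t-test on the slope."""
    if np.ptp(design.attr_diff) == 0:
        return SingleFit(np.nan, np.nan, np.nan, np.nan, "constant_diff")
    X = design.design_matrix()
    yv = design.response
    beta, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    df = len(yv) - X.shape[1]
    if df <= 0 or rank < X.shape[1]:
        return SingleFit(np.nan, np.nan, np.nan, np.nan, "constant_diff")
    rss = float(resid @ resid)
    scale = max(1.0, float(np.abs(yv).max()) ** 2)
    if rss <= 1e-18 * scale * len(yv):
        # response is an exact linear function of the diff (or constant)
        if abs(beta[1]) <= 1e-10 * np.sqrt(scale):
            return SingleFit(0.0, 0.0, 0.0, 0.5)
        t = np.inf if beta[1] > 0 else -np.inf
        return SingleFit(float(beta[1]), 0.0, float(t), float(stats.t.sf(t, df)))
    sigma2 = rss / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    t = float(beta[1] / se)
    return SingleFit(float(beta[1]), se, t, float(stats.t.sf(t, df)))


def adjust_pvalues(p_list, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment (NaNs pass through, not counted as tests)."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p.copy()
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if not mask.any():
        return out
    from statsmodels.stats.multitest import multipletests

    if method == "bonferroni":
        out[mask] = np.minimum(p[mask] * mask.sum(), 1.0)
    elif method in ("benjamini-hochberg", "fdr_bh", "bh"):
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return out


def _grouped_counts(dosage, i_idx, j_idx, weights=None):
    """Per-SNP tallies of |g_i - g_j| in {0,1,2} over pairs.

    Returns (counts, wsums): counts[s, l] = number of pairs at level l;
    wsums[s, l] = sum of ``weights`` over those pairs (None -> skipped).
    Boolean weights (the miss indicator) use pure integer counting on the
    weight-1 row subset; real weights fall back to a float32 matmul.
    Chunked over SNPs to bound memory at ~n_pairs x _SNP_CHUNK bytes.
    """
    n_snps = dosage.shape[1]
    counts = np.empty((n_snps, 3), dtype=np.int64)
    wsums = None if weights is None else np.empty((n_snps, 3))
    binary_w = weights is not None and np.isin(weights, (0.0, 1.0)).all()
    if binary_w:
        w_rows = np.asarray(weights, dtype=bool)
    elif weights is not None:
        w64 = np.asarray(weights, dtype=np.float64)
    chunk = _SNP_CHUNK if weights is None or binary_w else 64
    for start in range(0, n_snps, chunk):
        sl = slice(start, min(start + chunk, n_snps))
        di = np.abs(dosage[i_idx, sl].astype(np.int8) - dosage[j_idx, sl].astype(np.int8))
        di_w = di[w_rows] if weights is not None and binary_w else None
        for lvl in range(3):
            mask = di == lvl
            counts[sl, lvl] = mask.sum(axis=0)
            if weights is None:
                continue
            if binary_w:
                wsums[sl, lvl] = (di_w == lvl).sum(axis=0)
            else:
                wsums[sl, lvl] = w64 @ mask.astype(np.float64)
    return counts, wsums


def _rank_and_adjust(df: pd.DataFrame, adjust: str) -> pd.DataFrame:
    df = df.copy()
    df["p_adjusted"] = adjust_pvalues(df["p_one_sided"].to_numpy(), adjust)
    order = df.sort_values(["p_one_sided", "snp"], kind="stable", na_position="last").index
    ranks = pd.Series(np.arange(1, len(df) + 1), index=order)
    df["rank"] = ranks.reindex(df.index).astype(int)  # NA-p rows rank last
    return df


def run_npdr(G: GenotypeMatrix, y: PhenotypeVector,
             covars: CovariateTable | None = None, *, metric: str = "am",
             k: int | None = None, k_rule: str = "adaptive",
             neighborhood: str = "class-blind", q: float = 1.0,
             adjust: str = "bonferroni", dedup_pairs: bool = False,
             covar_scale: str = "range",
             pairs: NeighborPairSet | None = None) -> NpdrResult:
    """Run NPDR over every SNP, sharing one neighborhood.

    Neighbors are found in the full variant space with the same diff metric
    used for projection; covariates (if any) enter only the regressions.
    Per-SNP failures (monomorphic-in-neighborhood, separation) are flagged
    in the ``flag`` column, never raised.
    """
    if len(y) != G.n_samples:
        raise ValueError("phenotype length does not match genotype matrix")
    if covars is not None and covars.n_samples != G.n_samples:
        raise ValueError("covariate table length does not match genotype matrix")
    if G.has_missing:
        raise ValueError("missing genotypes present; run impute_mode first")
    m = G.n_samples
    if pairs is None:
        if k is None or k_rule == "adaptive":
            k_eff = adaptive_k(m) if k is None else k
        else:
            k_eff = k
        D = pairwise_distance(G, metric=metric, q=q)
        pairs = find_neighbors(D, k_eff, mode=neighborhood,
                               y=y if neighborhood == "hit-miss-balanced" else None)
    if dedup_pairs:
        pairs = pairs.dedup()
    i_idx, j_idx = pairs.i_idx, pairs.j_idx

    levels = np.array([0.0, 0.5, 1.0]) if metric == "am" else np.array([0.0, 1.0])

    if y.kind == "binary" and covars is None:
        miss = (y.values[i_idx] != y.values[j_idx]).astype(float)
        counts3, miss3 = _grouped_counts(G.dosage, i_idx, j_idx, weights=miss)
        if metric == "gm":
            counts = np.stack([counts3[:, 0], counts3[:, 1] + counts3[:, 2]], axis=1)
            misses = np.stack([miss3[:, 0], miss3[:, 1] + miss3[:, 2]], axis=1)
        else:
            counts, misses = counts3, miss3
        res = _glm.grouped_logistic(levels, counts, misses)
        beta, se1 = res["beta1"], res["se1"]
        stat = beta / se1
        p = stats.norm.sf(stat)
        flag = np.where(res["degenerate"], "constant_diff",
                        np.where(res["separated"], "separation", "ok"))
        bad = flag != "ok"
        beta, se1, stat, p = (np.where(bad, np.nan, v) for v in (beta, se1, stat, p))
        df = pd.DataFrame({"snp": G.snps, "beta": beta, "se": se1, "z": stat,
                           "p_one_sided": p, "flag": flag})
    elif y.kind == "continuous" and covars is None:
        resp = np.abs(y.values[i_idx] - y.values[j_idx])
        counts3, s3 = _grouped_counts(G.dosage, i_idx, j_idx, weights=resp)
        if metric == "gm":
            counts = np.stack([counts3[:, 0], counts3[:, 1] + counts3[:, 2]], axis=1)
            sums = np.stack([s3[:, 0], s3[:, 1] + s3[:, 2]], axis=1)
        else:
            counts, sums = counts3, s3
        res = _glm.grouped_linear(levels, counts, sums,
                                  float(resp.sum()), float(resp @ resp))
        beta, se1, dfree = res["beta1"], res["se1"], res["df"]
        stat = beta / se1
        p = stats.t.sf(stat, dfree)
        flag = np.where(res["degenerate"], "constant_diff", "ok")
        df = pd.DataFrame({"snp": G.snps, "beta": beta, "se": se1, "t": stat,
                           "p_one_sided": p, "flag": flag})
    else:
        # covariate-adjusted path: shared response and covariate diffs, one
        # dense GLM per SNP (warm-started from the covariates-only fit)
        if y.kind == "binary":
            resp = (y.values[i_idx] != y.values[j_idx]).astype(float)
        else:
            resp = np.abs(y.values[i_idx] - y.values[j_idx])
        cov_d, cov_names = _covariate_diffs(covars, i_idx, j_idx, covar_scale)
        start = None
        if y.kind == "binary" and len(np.unique(resp)) == 2:
            X0 = np.column_stack([np.ones(len(resp)), cov_d])
            fit0 = _glm.irls_logistic(X0, resp)
            if fit0.converged:
                start = np.insert(fit0.beta, 1, 0.0)
        rows = []
        fitter = fit_binary if y.kind == "binary" else fit_continuous
        for a in range(G.n_snps):
            attr = _diff_values(G.dosage[i_idx, a], G.dosage[j_idx, a], metric)
            design = ProjectedDesign(response=resp, attr_diff=attr,
                                     covar_diffs=cov_d, covar_names=cov_names,
                                     binary=(y.kind == "binary"))
            f = fitter(design, start=start) if y.kind == "binary" else fitter(design)
            rows.append((G.snps[a], f.beta, f.se, f.stat, f.p_one_sided, f.flag))
        stat_name = "z" if y.kind == "binary" else "t"
        df = pd.DataFrame(rows, columns=["snp", "beta", "se", stat_name,
                                         "p_one_sided", "flag"])

    df = _rank_and_adjust(df, adjust)
    meta = {"k": int(pairs.meta.get("k", -1)), "metric": metric,
            "neighborhood": pairs.meta.get("mode", "precomputed"),
            "q": q, "adjust": adjust, "n_pairs": pairs.n_pairs,
            "covariates": [] if covars is None else list(covars.names),
            "phenotype": y.kind}
    return NpdrResult(table=df, meta=meta)
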