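"""Comparison methods: univariate per-SNP regression and random forest.

Univariate association fits an additive-coding logistic (binary outcome)
or linear (continuous outcome) regression per SNP with a two-sided Wald
test.  Random-forest importance ranks SNPs by impurity decrease (fast,
default for high-dimensional runs) or permutation importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _glm
from .core import adjust_pvalues
from .io import GenotypeMatrix, PhenotypeVector

__all__ = ["RankingResult", "univariate_assoc", "rf_importance"]


@dataclass
class RankingResult:
    """Per-SNP scores and ranks for one ranking method."""

    table: pd.DataFrame
    method: str
    meta: dict = field(default_factory=dict)

    def ranks_of(self, snps) -> np.ndarray:
        lookup = dict(zip(self.table["snp"], self.table["rank"]))
        return np.array([lookup[s] for s in snps])

    def __len__(self) -> int:
        return len(self.table)


def _rank_by_p(df: pd.DataFrame) -> pd.DataFrame:
    order = df.sort_values(["p", "snp"], kind="stable", na_position="last").index
    ranks = pd.Series(np.arange(1, len(df) + 1), index=order)
    df = df.copy()
    df["rank"] = ranks.reindex(df.index).astype(int)
    return df


def univariate_assoc(G: GenotypeMatrix, y: PhenotypeVector,
                     adjust: str = "bonferroni") -> RankingResult:
    """Per-SNP additive-model regression of the phenotype on dosage.

    Two-sided Wald p per SNP; monomorphic SNPs yield NA.  Binary outcomes
    use a logistic fit on the 2x3 genotype-by-status table (exact MLE via
    grouped sufficient statistics), continuous outcomes a closed-form
    simple regression.
    """
    if len(y) != G.n_samples:
        raise ValueError("phenotype length does not match genotype matrix")
    X = G.dosage
    levels = np.array([0.0, 1.0, 2.0])
    if y.kind == "binary":
        cases = y.values == 1
        n_tot = np.stack([(X == g).sum(axis=0) for g in range(3)], axis=1)
        n_case = np.stack([((X == g) & cases[:, None]).sum(axis=0)
                           for g in range(3)], axis=1)
        res = _glm.grouped_logistic(levels, n_tot, n_case)
        beta, se = res["beta1"], res["se1"]
        stat = beta / se
        p = 2 * stats.norm.sf(np.abs(stat))
        bad = res["degenerate"] | res["separated"]
        beta, se, stat, p = (np.where(bad, np.nan, v) for v in (beta, se, stat, p))
    else:
        yv = y.values
        n = len(yv)
        Xf = X.astype(float)
        sx = Xf.sum(axis=0)
        sxx = (Xf * Xf).sum(axis=0)
        sxy = yv @ Xf
        sy, syy = yv.sum(), float(yv @ yv)
        den = n * sxx - sx * sx
        degen = den <= 1e-12
        den_safe = np.where(degen, 1.0, den)
        beta = (n * sxy - sx * sy) / den_safe
        b0 = (sy - beta * sx) / n
        rss = np.clip(syy - b0 * sy - beta * sxy, 0.0, None)
        se = np.sqrt(rss / (n - 2) * n / den_safe)
        stat = beta / se
        p = 2 * stats.t.sf(np.abs(stat), n - 2)
        beta, se, stat, p = (np.where(degen, np.nan, v) for v in (beta, se, stat, p))
    df = pd.DataFrame({"snp": G.snps, "score": -np.log10(np.clip(p, 1e-300, None)),
                       "beta": beta, "se": se, "stat": stat, "p": p})
    df["p_adjusted"] = adjust_pvalues(p, adjust)
    df = _rank_by_p(df)
    return RankingResult(df, "univariate", {"phenotype": y.kind, "adjust": adjust})


def rf_importance(G: GenotypeMatrix, y: PhenotypeVector, n_trees: int = 500,
                  importance: str = "impurity", seed: int | None = None,
                  n_permutations: int = 5) -> RankingResult:
    """Random-forest importance ranking of SNPs (descending score).

    ``importance='impurity'`` uses mean impurity decrease (computed during
    the fit); ``'permutation'`` uses out-of-sample permutation importance
    with ``n_permutations`` shuffles.  Ties break by SNP column order.
    """
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

    if len(y) != G.n_samples:
        raise ValueError("phenotype length does not match genotype matrix")
    cls = RandomForestClassifier if y.kind == "binary" else RandomForestRegressor
    model = cls(n_estimators=n_trees, random_state=seed, n_jobs=1)
    Xf = G.dosage.astype(np.float32)
    model.fit(Xf, y.values)
    if importance == "impurity":
        scores = model.feature_importances_
    elif importance == "permutation":
        from sklearn.inspection import permutation_importance

        perm = permutation_importance(model, Xf, y.values,
                                      n_repeats=n_permutations, random_state=seed)
        scores = perm.importances_mean
    else:
        raise ValueError(f"unknown importance kind {importance!r}")
    df = pd.DataFrame({"snp": G.snps, "score": scores})
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    df["rank"] = ranks
    return RankingResult(df, f"rf-{importance}",
                         {"n_trees": n_trees, "seed": seed, "phenotype": y.kind})
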