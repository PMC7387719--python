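"""Pairwise SNP-SNP interaction testing and epistasis-network construction.

For each unordered SNP pair a logistic model

    y ~ g1 + g2 + g1*g2 (+ covariate main effects)

is fitted with additive dosage coding; the two-sided Wald p of the product
term measures statistical epistasis.  P-values are adjusted across all
tested pairs and pairs below the significance threshold become network
edges weighted by -log10(adjusted p).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import adjust_pvalues
from .io import CovariateTable, GenotypeMatrix, PhenotypeVector

__all__ = ["InteractionNetwork", "interaction_test", "build_network"]

_WEIGHT_P_FLOOR = 1e-300  # avoids infinite -log10 weights on underflow


@dataclass
class InteractionNetwork:
    """Edge list, degree table and graph of significant pairwise interactions."""

    edges: pd.DataFrame  # snp1, snp2, p, p_adjusted, weight
    graph: nx.Graph
    n_tests: int
    alpha: float
    adjust: str
    meta: dict = field(default_factory=dict)

    @property
    def degree_table(self) -> pd.DataFrame:
        deg = sorted(self.graph.degree, key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(deg, columns=["snp", "degree"])

    def hub(self) -> tuple[str, int] | None:
        """Highest-degree node, ties broken by SNP ID."""
        if self.graph.number_of_edges() == 0:
            return None
        snp, deg = max(self.graph.degree, key=lambda kv: (kv[1], kv[0]))
        return snp, deg

    def write_edges(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def interaction_test(g1, g2, y: PhenotypeVector,
                     covars: CovariateTable | None = None) -> float:
    """Wald p for the g1 x g2 product term in a logistic model (NaN on failure).

    Failure modes — perfect separation, collinearity (e.g. g1 == g2),
    constant columns — return NaN rather than raising.
    """
    import statsmodels.api as sm

    if y.kind != "binary":
        raise ValueError("interaction_test requires a binary phenotype")
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        return float("nan")
    cols = [np.ones_like(g1), g1, g2, g1 * g2]
    if covars is not None:
        cols.append(covars.values)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return float("nan")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y.values, X).fit(disp=0, maxiter=200, method="lbfgs")
        p = float(fit.pvalues[3])
        if not np.isfinite(p) or abs(fit.params[3]) > 30:
            return float("nan")
        return p
    except Exception:
        return float("nan")


def build_network(G: GenotypeMatrix, y: PhenotypeVector,
                  covars: CovariateTable | None = None, alpha: float = 1e-6,
                  adjust: str = "benjamini-hochberg") -> InteractionNetwork:
    """Test all unordered SNP pairs and keep edges with adjusted p < alpha.

    Adjustment spans exactly the non-NA tested pairs (count recorded in
    ``n_tests``).  An empty edge set is a valid empty network; all input
    SNPs appear as nodes regardless.
    """
    snps = G.snps
    pairs = list(itertools.combinations(range(G.n_snps), 2))
    pvals = np.array([interaction_test(G.dosage[:, i], G.dosage[:, j], y, covars)
                      for i, j in pairs])
    adj = adjust_pvalues(pvals, adjust)
    n_tests = int((~np.isnan(pvals)).sum())
    rows = []
    graph = nx.Graph()
    graph.add_nodes_from(snps)
    for (i, j), p, pa in zip(pairs, pvals, adj):
        if np.isnan(pa) or pa >= alpha:
            continue
        weight = float(-np.log10(max(pa, _WEIGHT_P_FLOOR)))
        rows.append((snps[i], snps[j], p, pa, weight))
        graph.add_edge(snps[i], snps[j], weight=weight, p=p, p_adjusted=pa)
    edges = pd.DataFrame(rows, columns=["snp1", "snp2", "p", "p_adjusted", "weight"])
    edges = edges.sort_values("p_adjusted", kind="stable").reset_index(drop=True)
    return InteractionNetwork(edges=edges, graph=graph, n_tests=n_tests,
                              alpha=alpha, adjust=adjust,
                              meta={"covariates": [] if covars is None else list(covars.names)})
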