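import numpy as np
import pandas as pd
import pytest
from scipy import stats

import npdr
from npdr.core import (ProjectedDesign, adjust_pvalues, build_design,
                       fit_binary, fit_continuous)
from npdr.neighbors import NeighborPairSet, find_neighbors, pairwise_distance


def _complete_pairs(m):
    i, j = np.nonzero(~np.eye(m, dtype=bool))
    return NeighborPairSet(i, j, np.full(m, m - 1), {"k": m - 1})


# ---------------------------------------------------------------- fit_binary

def test_fit_binary_matches_two_by_two_closed_form():
    """Binary diff: the logistic slope is the log odds-ratio of the 2x2
    pair table.  Misses have diff 1 at rate 0.8, hits at rate 0.2:
    beta = log(0.8/0.2 * 0.8/0.2) = log 16 = 2.77."""
    n = 500
    resp, diff = [], []
    for miss in (0, 1):
        rate = 0.8 if miss else 0.2
        k = int(rate * n)
        resp += [miss] * n
        diff += [1.0] * k + [0.0] * (n - k)
    design = ProjectedDesign(np.array(resp, float), np.array(diff))
    fit = fit_binary(design)
    assert fit.beta == pytest.approx(np.log(16), abs=0.01)
    assert fit.flag == "ok" and fit.p_one_sided < 1e-10


def test_fit_binary_matches_grid_search_oracle():
    """MLE on a 50-pair design agrees with brute-force likelihood grid search."""
    rng = np.random.default_rng(3)
    diff = rng.choice([0.0, 0.5, 1.0], size=50)
    resp = (rng.random(50) < 0.3 + 0.4 * diff).astype(float)
    design = ProjectedDesign(resp, diff)
    fit = fit_binary(design)

    def nll(b0, b1):
        eta = b0 + b1 * diff
        return -np.sum(resp * eta - np.logaddexp(0, eta))

    b0g = np.linspace(fit.beta * 0 - 4, 4, 401)
    b1g = np.linspace(-6, 6, 601)
    vals = np.array([[nll(a, b) for b in b1g] for a in b0g])
    i0, i1 = np.unravel_index(vals.argmin(), vals.shape)
    # refine around the grid optimum
    b0g2 = np.linspace(b0g[i0] - 0.05, b0g[i0] + 0.05, 101)
    b1g2 = np.linspace(b1g[i1] - 0.05, b1g[i1] + 0.05, 101)
    vals2 = np.array([[nll(a, b) for b in b1g2] for a in b0g2])
    _, j1 = np.unravel_index(vals2.argmin(), vals2.shape)
    assert fit.beta == pytest.approx(b1g2[j1], abs=1e-3)


def test_fit_binary_flags_constant_diff_and_separation():
    const = ProjectedDesign(np.array([0.0, 1.0] * 10), np.zeros(20))
    assert fit_binary(const).flag == "constant_diff"
    # perfectly separated: diff 1 iff miss
    resp = np.array([0.0] * 10 + [1.0] * 10)
    sep = ProjectedDesign(resp, resp.copy())
    assert fit_binary(sep).flag == "separation"


def test_fit_binary_null_behavior():
    rng = np.random.default_rng(8)
    betas, ps = [], []
    for _ in range(40):
        diff = rng.choice([0.0, 0.5, 1.0], size=400)
        resp = rng.integers(0, 2, size=400).astype(float)
        f = fit_binary(ProjectedDesign(resp, diff))
        betas.append(f.beta)
        ps.append(f.p_one_sided)
    assert abs(np.mean(betas)) < 0.1
    # one-sided p approximately uniform under the null
    assert 0.25 < np.mean(ps) < 0.75
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ------------------------------------------------------------ fit_continuous

def test_fit_continuous_exact_linear_and_flat_cases():
    diff = np.array([0.0, 0.5, 1.0] * 10)
    exact = ProjectedDesign(2.0 * diff, diff, binary=False)
    f = fit_continuous(exact)
    assert f.beta == pytest.approx(2.0, abs=1e-10)
    assert f.p_one_sided < 1e-12
    flat = ProjectedDesign(np.full(30, 1.3), diff, binary=False)
    g = fit_continuous(flat)
    assert g.beta == pytest.approx(0.0, abs=1e-10)
    assert g.p_one_sided == pytest.approx(0.5, abs=1e-10)


def test_fit_continuous_matches_normal_equations_oracle():
    rng = np.random.default_rng(5)
    diff = rng.choice([0.0, 0.5, 1.0], size=60)
    resp = 0.4 + 0.9 * diff + rng.normal(0, 0.3, 60)
    f = fit_continuous(ProjectedDesign(resp, diff, binary=False))
    X = np.column_stack([np.ones(60), diff])
    beta_hat = np.linalg.solve(X.T @ X, X.T @ resp)
    resid = resp - X @ beta_hat
    sigma2 = resid @ resid / 58
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    assert f.beta == pytest.approx(beta_hat[1], abs=1e-9)
    assert f.se == pytest.approx(se, abs=1e-9)
    assert f.p_one_sided == pytest.approx(stats.t.sf(beta_hat[1] / se, 58), abs=1e-9)


# ---------------------------------------------------------------- adjustment

def test_adjust_pvalues_worked_examples():
    assert adjust_pvalues([0.001], "bonferroni")[0] == pytest.approx(0.001)
    p20 = [0.001] + [0.5] * 19
    assert adjust_pvalues(p20, "bonferroni")[0] == pytest.approx(0.02)
    bh = adjust_pvalues([0.01, 0.02, 0.03, 0.9], "benjamini-hochberg")
    np.testing.assert_allclose(bh, [0.04, 0.04, 0.04, 0.9])
    assert adjust_pvalues([], "bonferroni").size == 0
    out = adjust_pvalues([0.01, np.nan], "bonferroni")
    assert out[0] == pytest.approx(0.01) and np.isnan(out[1])


# -------------------------------------------------------------- build_design

def test_build_design_responses_and_cardinality(tiny_genotypes):
    G = tiny_genotypes
    y = npdr.PhenotypeVector(np.array([0.0, 0.0, 1.0, 1.0]), "binary")
    pairs = _complete_pairs(4)
    d = build_design(pairs, G, "A", y)
    assert d.n_pairs == 4 * 3
    same = y.values[pairs.i_idx] == y.values[pairs.j_idx]
    assert (d.response[same] == 0).all() and (d.response[~same] == 1).all()
    # AM diff of genotypes (0,1) is 0.5
    k = np.flatnonzero((pairs.i_idx == 0) & (pairs.j_idx == 1))[0]
    assert d.attr_diff[k] == 0.5


def test_build_design_drops_constant_covariate(tiny_genotypes):
    G = tiny_genotypes
    y = npdr.PhenotypeVector(np.array([0.0, 1.0, 0.0, 1.0]), "binary")
    covars = npdr.CovariateTable(["c1", "c2"],
                                 np.column_stack([np.ones(4), [0.1, 0.4, 0.2, 0.9]]))
    with pytest.warns(UserWarning, match="constant covariates"):
        d = build_design(_complete_pairs(4), G, 0, y, covars)
    assert d.covar_names == ["c2"]
    assert d.covar_diffs.shape == (12, 1)
    assert d.covar_diffs.max() == pytest.approx(1.0)  # range-scaled


# ------------------------------------------------------------------ run_npdr

def test_run_npdr_grouped_path_equals_per_snp_fits(small_epistasis_dataset):
    """The batched sufficient-statistic fits must reproduce the dense
    per-pair GLM exactly, SNP by SNP."""
    G, y, _ = small_epistasis_dataset
    res = npdr.run_npdr(G, y, metric="am")
    D = pairwise_distance(G, metric="am")
    pairs = find_neighbors(D, res.meta["k"])
    for a in [0, 7, 13, 19]:
        f = fit_binary(build_design(pairs, G, a, y))
        row = res.table.iloc[a]
        assert row["beta"] == pytest.approx(f.beta, abs=1e-6)
        assert row["se"] == pytest.approx(f.se, abs=1e-6)
        assert row["p_one_sided"] == pytest.approx(f.p_one_sided, abs=1e-8)


def test_run_npdr_continuous_grouped_path_equals_per_snp_fits():
    G, y, _ = npdr.simulate_design("continuous-pair", seed=21, n=150)
    res = npdr.run_npdr(G, y)
    D = pairwise_distance(G)
    pairs = find_neighbors(D, res.meta["k"])
    for a in [0, 11, 19]:
        f = fit_continuous(build_design(pairs, G, a, y))
        row = res.table.iloc[a]
        assert row["beta"] == pytest.approx(f.beta, rel=1e-9, abs=1e-12)
        assert row["se"] == pytest.approx(f.se, rel=1e-7, abs=1e-12)


def test_run_npdr_column_permutation_invariance(small_epistasis_dataset):
    G, y, _ = small_epistasis_dataset
    rng = np.random.default_rng(0)
    perm = rng.permutation(G.n_snps)
    Gp = G.subset_snps(perm)
    res = npdr.run_npdr(G, y).table.set_index("snp")
    resp = npdr.run_npdr(Gp, y).table.set_index("snp")
    for s in G.snps:
        assert resp.loc[s, "beta"] == pytest.approx(res.loc[s, "beta"], abs=1e-9)
        assert resp.loc[s, "rank"] == res.loc[s, "rank"]


def test_run_npdr_flags_monomorphic_snp_without_aborting(small_epistasis_dataset):
    G, y, _ = small_epistasis_dataset
    dosage = G.dosage.copy()
    dosage[:, 5] = 1  # monomorphic column
    Gm = npdr.GenotypeMatrix(list(G.samples), list(G.snps), dosage)
    res = npdr.run_npdr(Gm, y)
    row = res.table.iloc[5]
    assert row["flag"] == "constant_diff" and np.isnan(row["p_one_sided"])
    assert (res.table["flag"] == "ok").sum() == 19
    # ranks are a permutation with the flagged SNP last
    assert sorted(res.table["rank"]) == list(range(1, 21))
    assert res.table.iloc[5]["rank"] == 20


def test_run_npdr_detects_epistatic_pair(benchmark_epistasis_dataset):
    G, y, truth = benchmark_epistasis_dataset
    res = npdr.run_npdr(G, y)
    tab = res.table.set_index("snp")
    assert set(res.top(2)["snp"]) == set(truth.functional_snps)
    for s in truth.functional_snps:
        assert tab.loc[s, "p_adjusted"] < 0.05


def test_dedup_pairs_restore_far_tail_calibration():
    """With unordered unique pairs the permutation-null far tail is close to
    nominal; the ordered-pair default double-counts reciprocal pairs and is
    anti-conservative there (documented limitation)."""
    G, y, _ = npdr.simulate_design("interact-pair", seed=7, h2=0.4,
                                   n_cases=100, n_controls=100)
    D = pairwise_distance(G)
    pairs = find_neighbors(D, npdr.adaptive_k(200))
    rng = np.random.default_rng(1)
    discoveries = 0
    for _ in range(20):
        yp = npdr.PhenotypeVector(rng.permutation(y.values), "binary")
        tab = npdr.run_npdr(G, yp, pairs=pairs, dedup_pairs=True).table
        discoveries += int((tab["p_adjusted"] < 0.05).any())
    assert discoveries <= 1


def test_run_npdr_dedup_pairs_option(small_epistasis_dataset):
    G, y, _ = small_epistasis_dataset
    res = npdr.run_npdr(G, y, dedup_pairs=True)
    assert res.meta["n_pairs"] < npdr.run_npdr(G, y).meta["n_pairs"]
    tab = res.table.set_index("snp")
    assert set(res.top(2)["snp"]) <= set(G.snps)
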