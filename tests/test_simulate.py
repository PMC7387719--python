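import numpy as np
import pytest
from scipy import stats

import npdr
from npdr.simulate import (DESIGNS, FeasibilityError, hwe_frequencies,
                           make_epistasis_penetrance, make_main_effect_model,
                           nearest_neighbor_signal, realized_heritability,
                           simulate_design)


def brute_force_h2(table, maf):
    """Independent enumeration over all genotype cells."""
    w = hwe_frequencies(maf)
    table = np.asarray(table, float)
    W = w if table.ndim == 1 else np.outer(w, w)
    K = sum(W.ravel()[i] * table.ravel()[i] for i in range(table.size))
    num = sum(W.ravel()[i] * (table.ravel()[i] - K) ** 2 for i in range(table.size))
    return num / (K * (1 - K)), K


def test_epistasis_table_exact_h2_and_flat_marginals():
    m = make_epistasis_penetrance(maf=0.2, h2=0.4, K=0.3, rng=0)
    h2, K = brute_force_h2(m.table, 0.2)
    assert h2 == pytest.approx(0.4, abs=1e-9)
    assert K == pytest.approx(0.3, abs=1e-9)
    # pure epistasis: every single-locus marginal penetrance equals K
    np.testing.assert_allclose(m.marginal_penetrance(0), 0.3, atol=1e-10)
    np.testing.assert_allclose(m.marginal_penetrance(1), 0.3, atol=1e-10)


def test_epistasis_table_null_model_and_feasibility_error():
    m0 = make_epistasis_penetrance(h2=0.0)
    np.testing.assert_allclose(m0.table, 0.3)
    with pytest.raises(FeasibilityError):
        make_epistasis_penetrance(maf=0.2, h2=0.9, K=0.01, rng=0, max_tries=3000)


def test_model_selection_increases_detectability_signal():
    rng = np.random.default_rng(7)
    unselected = [nearest_neighbor_signal(
        make_epistasis_penetrance(rng=rng).table, 0.2) for _ in range(10)]
    selected = nearest_neighbor_signal(
        make_epistasis_penetrance(rng=8, select_best_of=50).table, 0.2)
    assert selected >= np.median(unselected)


def test_seeded_determinism_bit_identical():
    a = simulate_design("interact-pair", seed=5)
    b = simulate_design("interact-pair", seed=5)
    np.testing.assert_array_equal(a[0].dosage, b[0].dosage)
    np.testing.assert_array_equal(a[1].values, b[1].values)
    assert a[2].functional_snps == b[2].functional_snps
    c = simulate_design("interact-pair", seed=6)
    assert not np.array_equal(a[0].dosage, c[0].dosage)


def test_case_control_shapes_and_imbalanced_design():
    G, y, truth = simulate_design("interact-pair", seed=1, h2=0.4)
    assert (G.n_samples, G.n_snps) == (1600, 20)
    assert y.values.sum() == 800  # 800 cases, 800 controls
    assert len(truth.functional_snps) == 2
    Gi, yi, _ = simulate_design("imbalanced-pair", seed=1)
    assert yi.values.sum() == 960 and (yi.values == 0).sum() == 640


def test_null_h2_leaves_functional_snps_indistinguishable():
    """With h2 = 0, case-control allele-frequency differences at functional
    loci match the background across replicates."""
    diffs_func, diffs_bg = [], []
    for seed in range(12):
        G, y, truth = simulate_design("interact-pair", seed=seed, h2=0.0,
                                      n_cases=200, n_controls=200)
        cases = y.values == 1
        fdiff = (G.dosage[cases].mean(axis=0) - G.dosage[~cases].mean(axis=0)) / 2
        fi = truth.functional_indices
        diffs_func += list(fdiff[fi])
        diffs_bg += [fdiff[k] for k in range(G.n_snps) if k not in fi]
    t = stats.ttest_ind(np.abs(diffs_func), np.abs(diffs_bg))
    assert t.pvalue > 0.01


def test_continuous_outcome_heritability_and_background_independence():
    G, y, truth = simulate_design("continuous-pair", seed=3, h2=0.4)
    model = truth.models[0]
    dev = model.table - model.prevalence
    fi = truth.functional_indices
    score = dev[G.dosage[:, fi[0]], G.dosage[:, fi[1]]]
    ss_res = np.sum((y.values - score) ** 2)
    ss_tot = np.sum((y.values - y.values.mean()) ** 2)
    r2 = 1 - ss_res / ss_tot
    assert r2 == pytest.approx(0.4, abs=0.05)
    bg = [k for k in range(G.n_snps) if k not in fi]
    r = [abs(stats.pearsonr(G.dosage[:, k], y.values)[0]) for k in bg]
    assert max(r) < 0.1


def test_continuous_high_h2_limit_nearly_deterministic():
    G, y, truth = simulate_design("continuous-pair", seed=4, h2=0.99, n=400)
    model = truth.models[0]
    dev = model.table - model.prevalence
    fi = truth.functional_indices
    score = dev[G.dosage[:, fi[0]], G.dosage[:, fi[1]]]
    assert np.corrcoef(score, y.values)[0, 1] ** 2 > 0.95


def test_main_effect_pair_splits_h2_equally():
    G, y, truth = simulate_design("main-pair", seed=2)
    assert truth.extra["mode"] == "additive"
    for m in truth.models:
        h2_l, _ = brute_force_h2(m.table, m.maf)
        assert h2_l == pytest.approx(0.2, abs=1e-9)  # h2/2 per locus


def test_main_effects_detected_by_univariate_baseline():
    G, y, truth = simulate_design("main-pair", seed=9)
    res = npdr.univariate_assoc(G, y)
    tab = res.table.set_index("snp")
    for s in truth.functional_snps:
        assert tab.loc[s, "p_adjusted"] < 0.05


def test_main_effect_null_h2_gives_flat_model():
    m = make_main_effect_model(h2=0.0)
    np.testing.assert_allclose(m.table, 0.3)


def test_heterogeneous_pairs_have_no_marginal_effects():
    """All four functional SNPs of the two-pair heterogeneity design are
    marginally null: single-locus chi-square p's look uniform."""
    ps = []
    for seed in range(8):
        G, y, truth = simulate_design("interact-4", seed=seed,
                                      n_cases=250, n_controls=250)
        cases = y.values == 1
        for k in truth.functional_indices:
            obs = np.array([np.bincount(G.dosage[rows, k], minlength=3)
                            for rows in (cases, ~cases)])
            keep = obs.sum(axis=0) > 0
            ps.append(stats.chi2_contingency(obs[:, keep])[1])
    assert np.mean(np.array(ps) < 0.05) < 0.2
    assert stats.kstest(ps, "uniform").pvalue > 0.001


def test_heterogeneous_assignment_prob_one_reduces_to_single_pair():
    G, y, truth = npdr.simulate_heterogeneous_pairs(
        h2=0.4, n_cases=150, n_controls=150, assign_prob=1.0, seed=0)
    res = npdr.run_npdr(G, y)
    # only pair 1 (M1, M2) governs disease; its SNPs outrank pair 2's
    tab = res.table.set_index("snp")
    assert tab.loc["M1", "rank"] + tab.loc["M2", "rank"] < \
        tab.loc["M3", "rank"] + tab.loc["M4", "rank"]


def test_background_maf_converges(small_epistasis_dataset):
    G, y, truth = small_epistasis_dataset
    bg = [k for k in range(G.n_snps) if k not in truth.functional_indices]
    mafs = G.dosage[:, bg].mean(axis=0) / 2
    assert abs(mafs.mean() - 0.2) < 0.05  # small-m sanity; tight check at p=10^4


def test_design_registry_matches_benchmark_table():
    assert DESIGNS["interact-pair"].h2 == 0.05
    assert DESIGNS["highdim-pair"].p_total == 10_000
    assert (DESIGNS["imbalanced-pair"].n_cases,
            DESIGNS["imbalanced-pair"].n_controls) == (960, 640)
    assert DESIGNS["continuous-pair"].n == 1600
    with pytest.raises(ValueError):
        simulate_design("no-such-design")
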