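import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import npdr
from npdr.neighbors import (adaptive_k, diff_am, diff_gm, find_neighbors,
                            pairwise_distance)

dosages = st.integers(min_value=0, max_value=2)


@pytest.mark.parametrize("g1,g2,gm,am", [
    (0, 0, 0.0, 0.0),
    (1, 1, 0.0, 0.0),
    (1, 2, 1.0, 0.5),
    (0, 1, 1.0, 0.5),
    (2, 0, 1.0, 1.0),
])
def test_diff_worked_values(g1, g2, gm, am):
    assert diff_gm(g1, g2) == gm
    assert diff_am(g1, g2) == am


@settings(max_examples=50, deadline=None, derandomize=True)
@given(g1=dosages, g2=dosages)
def test_diffs_symmetric_and_bounded(g1, g2):
    for d in (diff_gm, diff_am):
        assert d(g1, g2) == d(g2, g1)
        assert 0.0 <= d(g1, g2) <= 1.0
        assert d(g1, g1) == 0.0


def test_diff_rejects_missing_and_bad_dosage():
    with pytest.raises(ValueError):
        diff_am(np.nan, 1)
    with pytest.raises(ValueError):
        diff_gm(3, 1)


def test_manhattan_distance_hand_example():
    G = npdr.GenotypeMatrix(["s1", "s2"], ["a", "b"],
                            np.array([[0, 0], [2, 1]], dtype=np.int8))
    D = pairwise_distance(G, metric="am", q=1)
    assert D[0, 1] == pytest.approx(1.5)  # 1 + 0.5
    assert D[1, 0] == pytest.approx(1.5) and D[0, 0] == 0.0


def test_distance_matches_brute_force_double_loop():
    rng = np.random.default_rng(0)
    X = rng.integers(0, 3, size=(10, 5)).astype(np.int8)
    G = npdr.GenotypeMatrix([f"s{i}" for i in range(10)],
                            [f"v{j}" for j in range(5)], X)
    for metric, diff in (("am", diff_am), ("gm", diff_gm)):
        for q in (1.0, 2.0):
            D = pairwise_distance(G, metric=metric, q=q)
            for i in range(10):
                for j in range(10):
                    expected = np.sum([diff(X[i, a], X[j, a]) ** q
                                       for a in range(5)]) ** (1 / q)
                    assert D[i, j] == pytest.approx(expected, abs=1e-6)


def test_distance_rejects_q_below_one(tiny_genotypes):
    with pytest.raises(ValueError):
        pairwise_distance(tiny_genotypes, q=0.5)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.lists(dosages, min_size=4, max_size=4), min_size=3, max_size=8))
def test_manhattan_diff_distance_triangle_inequality(rows):
    X = np.array(rows, dtype=np.int8)
    D = pairwise_distance(X, metric="am", q=1)
    m = len(rows)
    for i in range(m):
        for j in range(m):
            for k in range(m):
                assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


def test_adaptive_k_values():
    assert adaptive_k(1600) == 246  # floor(0.154 * 1599)
    assert adaptive_k(2) == 1  # clamped from floor = 0
    # fraction converges to 0.154 for large m
    m = 10**6
    assert adaptive_k(m) / (m - 1) == pytest.approx(0.154, abs=1e-5)


def test_find_neighbors_collinear_points():
    # points at 0, 1, 3 on a line: both endpoints pick the middle
    D = np.abs(np.subtract.outer([0.0, 1.0, 3.0], [0.0, 1.0, 3.0]))
    pairs = find_neighbors(D, k=1)
    nbr = dict(zip(pairs.i_idx, pairs.j_idx))
    assert nbr[0] == 1 and nbr[2] == 1


def test_find_neighbors_matches_full_sort_oracle():
    rng = np.random.default_rng(1)
    D = rng.random((20, 20))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    k = 5
    pairs = find_neighbors(D, k)
    got = {i: set() for i in range(20)}
    for i, j in zip(pairs.i_idx, pairs.j_idx):
        got[i].add(j)
    for i in range(20):
        row = [(D[i, j], j) for j in range(20) if j != i]
        expect = {j for _, j in sorted(row)[:k]}
        assert got[i] == expect


def test_complete_neighborhood_limit():
    rng = np.random.default_rng(2)
    D = rng.random((6, 6))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    pairs = find_neighbors(D, k=5)
    assert pairs.n_pairs == 6 * 5
    assert pairs.n_pairs == pairs.k_per.sum()
    assert len({(i, j) for i, j in zip(pairs.i_idx, pairs.j_idx)}) == 30


def test_tie_break_by_instance_index():
    D = np.zeros((4, 4))  # all distances tied
    pairs = find_neighbors(D, k=2)
    by_i = {i: [] for i in range(4)}
    for i, j in zip(pairs.i_idx, pairs.j_idx):
        by_i[i].append(j)
    assert by_i[0] == [1, 2] and by_i[3] == [0, 1]


def test_hit_miss_balanced_mode(small_epistasis_dataset):
    G, y, _ = small_epistasis_dataset
    D = pairwise_distance(G)
    pairs = find_neighbors(D, k=5, mode="hit-miss-balanced", y=y)
    yv = y.values
    # every instance contributes 5 hit and 5 miss neighbors
    assert pairs.n_pairs == G.n_samples * 10
    same = yv[pairs.i_idx] == yv[pairs.j_idx]
    assert same.sum() == G.n_samples * 5
    with pytest.raises(ValueError):
        find_neighbors(D, k=5, mode="hit-miss-balanced", y=None)
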