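"""Active-learning strategies against brute-force oracles, plus the loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare
from sklearn.cluster import KMeans

import ethoclust as ec
from ethoclust.selection import _unlabeled_indices

from reference import brute_coreset, brute_mi, brute_top


# ---------------------------------------------------------------------------
# cluster-center (top)

def test_top_two_blobs_picks_nearest_to_each_mean():
    Z = np.array([[0.0, 0.0], [0.4, 0.0], [10.0, 0.0], [10.5, 0.0]])
    sel = ec.select_top(Z, labeled=[], k=2, seed=0)
    # one pick per blob, each the member closest to its blob mean
    assert sorted(sel.chosen) == [1, 2]  # 0.4 is nearer 0.2; 10.0 nearer 10.25


def test_top_identical_points_tie_to_lowest_index():
    Z = np.ones((5, 3))
    sel = ec.select_top(Z, labeled=[], k=1, seed=0)
    assert sel.chosen == [0]


def test_top_k_equals_pool_returns_all():
    Z = np.random.default_rng(0).normal(size=(6, 2))
    sel = ec.select_top(Z, labeled=[1], k=5, seed=0)
    assert sorted(sel.chosen) == [0, 2, 3, 4, 5]


# ---------------------------------------------------------------------------
# core-set (cs)

def test_coreset_1d_worked_examples():
    Z = np.array([[0.0], [1.0], [10.0]])
    sel = ec.select_coreset(Z, labeled=[0], k=1)
    assert sel.chosen == [2]  # farthest from the labeled point at 0
    sel2 = ec.select_coreset(Z, labeled=[0], k=2)
    assert sel2.chosen == [2, 1]  # after 10, the point at 1 has min-dist 1


def test_coreset_bootstrap_without_labels():
    Z = np.array([[0.0], [2.0], [9.0]])  # mean 11/3; farthest is 9
    sel = ec.select_coreset(Z, labeled=[], k=2)
    assert sel.chosen[0] == 2
    assert sel.chosen == [2, 0]


def test_coreset_matches_brute_force_greedy():
    rng = np.random.default_rng(0)
    for trial in range(30):
        n = int(rng.integers(5, 60))
        m = int(rng.integers(1, 6))
        Z = rng.normal(size=(n, m))
        n_lab = int(rng.integers(0, n // 2 + 1))
        labeled = sorted(rng.choice(n, size=n_lab, replace=False).tolist())
        pool = _unlabeled_indices(n, labeled)
        k = int(rng.integers(1, min(6, pool.size) + 1))
        sel = ec.select_coreset(Z, labeled, k)
        assert sel.chosen == brute_coreset(Z, labeled, pool, k)


# ---------------------------------------------------------------------------
# margin / uncertainty (mi)

def test_mi_zero_margin_first():
    probs = np.array([[0.5, 0.5], [0.9, 0.1]])
    sel = ec.select_mi(probs, [0, 1], k=1)
    assert sel.chosen == [0]


def test_mi_uniform_before_peaked():
    probs = np.array([[0.8, 0.1, 0.1], [1 / 3, 1 / 3, 1 / 3]])
    sel = ec.select_mi(probs, [4, 9], k=2)
    assert sel.chosen == [9, 4]


def test_mi_matches_brute_force_sort():
    rng = np.random.default_rng(1)
    probs = rng.dirichlet(np.ones(4), size=20)
    pool = np.arange(20)
    sel = ec.select_mi(probs, pool, k=5)
    assert sel.chosen == brute_mi(probs, pool, 5)


def test_mi_entropy_variant():
    probs = np.array([[0.96, 0.02, 0.02], [0.5, 0.3, 0.2]])
    sel = ec.select_mi(probs, [0, 1], k=1, method="entropy")
    assert sel.chosen == [1]


# ---------------------------------------------------------------------------
# random baseline

def test_random_k_equals_n_returns_all_and_reproducible():
    sel = ec.select_random(6, labeled=[2], k=5, seed=0)
    assert sorted(sel.chosen) == [0, 1, 3, 4, 5]
    a = ec.select_random(50, labeled=[], k=10, seed=3)
    b = ec.select_random(50, labeled=[], k=10, seed=3)
    assert a.chosen == b.chosen


def test_random_is_uniform_chi_square():
    counts = np.zeros(5)
    for rep in range(10_000):
        sel = ec.select_random(5, labeled=[], k=1, seed=rep)
        counts[sel.chosen[0]] += 1
    assert chisquare(counts).pvalue > 0.001


# ---------------------------------------------------------------------------
# shared strategy invariants

@settings(max_examples=40, deadline=None)
@given(st.data())
def test_strategies_unique_disjoint_correct_length(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    n = data.draw(st.integers(4, 40))
    m = data.draw(st.integers(1, 5))
    Z = rng.normal(size=(n, m))
    n_lab = data.draw(st.integers(0, n - 2))
    labeled = sorted(rng.choice(n, size=n_lab, replace=False).tolist())
    pool = _unlabeled_indices(n, labeled)
    k = data.draw(st.integers(1, pool.size))
    strategy = data.draw(st.sampled_from(["top", "cs", "mi", "random"]))
    if strategy == "top":
        sel = ec.select_top(Z, labeled, k, seed=0)
    elif strategy == "cs":
        sel = ec.select_coreset(Z, labeled, k)
    elif strategy == "mi":
        probs = rng.dirichlet(np.ones(3), size=pool.size)
        sel = ec.select_mi(probs, pool, k)
    else:
        sel = ec.select_random(n, labeled, k, seed=0)
    assert len(sel.chosen) == k
    assert len(set(sel.chosen)) == k
    assert not set(sel.chosen) & set(labeled)


def test_k_larger_than_pool_clamps_with_warning():
    Z = np.zeros((4, 2))
    with pytest.warns(UserWarning, match="clamp"):
        sel = ec.select_coreset(Z, labeled=[0, 1], k=9)
    assert sorted(sel.chosen) == [2, 3]


# ---------------------------------------------------------------------------
# the iterative loop

def small_loop_setup(tiny_prepared, tiny_model_config):
    train_p, test_p, _ = tiny_prepared
    work = train_p.without_labels()
    oracle = ec.truth_oracle(train_p)
    return work, test_p, oracle


def test_loop_full_budget_labels_everything(tiny_prepared, tiny_model_config):
    work, test_p, oracle = small_loop_setup(tiny_prepared, tiny_model_config)
    alcfg = ec.ALConfig(strategy="random", budget_fractions=(1.0,), seed=0)
    ccfg = ec.ClassifierConfig(epochs=2, seed=0)
    _, hist = ec.al_loop(work, test_p, tiny_model_config, ccfg, alcfg, oracle)
    assert hist.iterations[-1]["n_labeled"] == len(work)
    assert work.labeled_mask.all()


def test_loop_mi_falls_back_to_top_then_uses_mi(tiny_prepared,
                                                tiny_model_config, caplog):
    import logging

    work, test_p, oracle = small_loop_setup(tiny_prepared, tiny_model_config)
    alcfg = ec.ALConfig(strategy="mi", budget_fractions=(0.1, 0.2), seed=0)
    ccfg = ec.ClassifierConfig(epochs=2, seed=0)
    with caplog.at_level(logging.INFO, logger="ethoclust.selection"):
        _, hist = ec.al_loop(work, test_p, tiny_model_config, ccfg, alcfg, oracle)
    assert "falling back" in caplog.text
    rows = hist.to_rows()
    assert [r["strategy"] for r in rows] == ["top", "mi"]
    # labeled counts monotone nondecreasing, accuracy recorded each iteration
    counts = [r["n_labeled"] for r in rows]
    assert counts == sorted(counts)
    assert all(0.0 <= r["test_accuracy"] <= 100.0 for r in rows)


def test_al_config_validation():
    with pytest.raises(ValueError, match="increasing"):
        ec.ALConfig(budget_fractions=(0.2, 0.1)).validate()
    with pytest.raises(ValueError, match="strategy"):
        ec.ALConfig(strategy="oracle").validate()
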