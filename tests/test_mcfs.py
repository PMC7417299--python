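"""MCFS: entropy/IG/wAcc, tree induction, relative importance, ranking.

Brute-force oracles here are deliberately naive (plain-Python frequency
tables, exhaustive split enumeration) and independent of the package's
vectorized paths.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

from pancnv.mcfs import (
    DecisionTree,
    Forest,
    MCFSConfig,
    MCFSConfigError,
    TreeNode,
    build_forest,
    build_tree,
    draw_subsets,
    entropy,
    forest_from_subsets,
    information_gain,
    mcfs_rank,
    predict_tree,
    relative_importance,
    ri_scores,
    weighted_accuracy,
)
from pancnv.synthetic import CohortSpec, generate_cohort


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def entropy_oracle(counts):
    total = sum(counts)
    return -sum(
        (c / total) * math.log2(c / total) for c in counts if c > 0
    )


def ig_oracle(parent, children):
    n = sum(parent)
    cond = sum(
        sum(ch) / n * entropy_oracle(ch) for ch in children if sum(ch) > 0
    )
    return entropy_oracle(parent) - cond


def wacc_oracle(conf):
    c = len(conf)
    return sum(conf[i][i] / sum(conf[i]) for i in range(c)) / c


def exhaustive_tree_oracle(X, y, n_classes, n_states):
    """Greedy max-IG tree by exhaustive enumeration of every
    (feature, threshold) binary ordinal split, plain Python throughout."""

    def class_counts(rows):
        counts = [0] * n_classes
        for i in rows:
            counts[y[i]] += 1
        return counts

    def grow(rows):
        parent = class_counts(rows)
        node = {
            "n": len(rows),
            "counts": parent,
            "pred": parent.index(max(parent)),
            "feature": None,
        }
        if sum(1 for c in parent if c > 0) <= 1 or len(rows) < 2:
            return node
        best = (-math.inf, None, None)
        for j in range(X.shape[1]):
            for thr in range(n_states - 1):
                left = [i for i in rows if X[i, j] <= thr]
                right = [i for i in rows if X[i, j] > thr]
                if not left or not right:
                    continue
                ig = ig_oracle(parent, [class_counts(left), class_counts(right)])
                if ig > best[0]:
                    best = (ig, j, thr)
        ig, j, thr = best
        if j is None or ig <= 1e-12:
            return node
        node.update(feature=j, threshold=thr, ig=ig)
        node["left"] = grow([i for i in rows if X[i, j] <= thr])
        node["right"] = grow([i for i in rows if X[i, j] > thr])
        return node

    return grow(list(range(X.shape[0])))


def assert_same_structure(node: TreeNode, oracle: dict):
    assert node.n_samples == oracle["n"]
    assert list(node.class_counts) == oracle["counts"]
    if oracle["feature"] is None:
        assert node.is_leaf
        return
    assert node.feature == oracle["feature"]
    assert node.threshold == oracle["threshold"]
    assert node.info_gain == pytest.approx(oracle["ig"], abs=1e-12)
    assert_same_structure(node.left, oracle["left"])
    assert_same_structure(node.right, oracle["right"])


def ri_oracle(forest, n_features, u, v):
    """Direct evaluation of the relative-importance sum, feature by
    feature, via an independent recursive traversal."""
    ri = [0.0] * n_features

    def walk(node, tree):
        if node.feature is None:
            return
        ri[node.feature] += (
            (tree.wacc ** u)
            * node.info_gain
            * (node.n_samples / tree.n_root) ** v
        )
        walk(node.left, tree)
        walk(node.right, tree)

    for tree in forest.trees:
        walk(tree.root, tree)
    return np.asarray(ri)


# ---------------------------------------------------------------------------
# entropy / IG / wAcc
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts, expected",
    [([4, 4], 1.0), ([8, 0], 0.0), ([3, 1], 0.8112781244591328)],
)
def test_entropy_known_values(counts, expected):
    assert entropy(counts) == pytest.approx(expected, abs=1e-12)


def test_entropy_rejects_empty_table():
    with pytest.raises(ValueError):
        entropy([0, 0])


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.lists(st.integers(0, 50), min_size=1, max_size=4).filter(lambda c: sum(c) > 0))
def test_entropy_matches_oracle_and_bounds(counts):
    h = entropy(counts)
    assert h == pytest.approx(entropy_oracle(counts), abs=1e-12)
    assert 0.0 <= h <= math.log2(len(counts)) + 1e-12


@pytest.mark.parametrize(
    "parent, children, expected",
    [
        ([4, 4], [[4, 0], [0, 4]], 1.0),
        ([8, 0], [[5, 0], [3, 0]], 0.0),
        ([4, 4], [[2, 2], [2, 2]], 0.0),
    ],
)
def test_information_gain_known_values(parent, children, expected):
    assert information_gain(parent, children) == pytest.approx(expected, abs=1e-12)


def test_information_gain_rejects_non_partition():
    with pytest.raises(ValueError):
        information_gain([4, 4], [[3, 0], [0, 4]])


@pytest.mark.parametrize(
    "conf, expected",
    [
        ([[10, 0], [0, 10]], 1.0),
        ([[5, 5], [0, 10]], 0.75),
        ([[0, 10], [10, 0]], 0.0),
    ],
)
def test_weighted_accuracy_known_values(conf, expected):
    assert weighted_accuracy(conf) == pytest.approx(expected, abs=1e-12)


def test_weighted_accuracy_rejects_empty_class_row():
    with pytest.raises(ValueError):
        weighted_accuracy([[0, 0], [3, 7]])


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def test_perfect_feature_gives_depth_one_tree():
    X = np.array([[0], [0], [0], [2], [2], [2]])
    y = np.array([0, 0, 0, 1, 1, 1])
    tree = build_tree(X, y, n_classes=2, n_states=3)
    assert tree.root.feature == 0
    assert tree.root.left.is_leaf and tree.root.right.is_leaf
    assert tree.root.info_gain == pytest.approx(1.0, abs=1e-12)
    # a held-out set following the same rule is classified perfectly
    assert np.array_equal(predict_tree(tree, X), y)


def test_constant_features_give_majority_leaf():
    X = np.ones((8, 3), dtype=int)
    y = np.array([0, 0, 0, 0, 0, 1, 1, 1])
    tree = build_tree(X, y, n_classes=2, n_states=2)
    assert tree.root.is_leaf
    assert tree.root.prediction == 0


def test_tree_matches_exhaustive_search_oracle_on_toy():
    rng = np.random.default_rng(17)
    X = rng.integers(0, 3, size=(12, 2))
    y = (X[:, 0] + rng.integers(0, 2, size=12) > 1).astype(int)
    tree = build_tree(X, y, n_classes=2, n_states=3)
    oracle = exhaustive_tree_oracle(X, y, n_classes=2, n_states=3)
    assert_same_structure(tree.root, oracle)


def test_tree_matches_exhaustive_oracle_on_random_instances():
    rng = np.random.default_rng(23)
    for _ in range(20):
        n = int(rng.integers(4, 21))
        m = int(rng.integers(1, 5))
        c = int(rng.integers(2, 4))
        X = rng.integers(0, 5, size=(n, m))
        y = rng.integers(0, c, size=n)
        tree = build_tree(X, y, n_classes=c, n_states=5)
        oracle = exhaustive_tree_oracle(X, y, n_classes=c, n_states=5)
        assert_same_structure(tree.root, oracle)


def test_child_counts_sum_to_parent(four_class_cohort):
    matrix, _ = four_class_cohort
    forest = build_forest(matrix, MCFSConfig(s=5, m=10, t=2, seed=1))
    for tree in forest.trees:
        for node in tree.internal_nodes():
            assert node.left.n_samples + node.right.n_samples == node.n_samples
            assert node.info_gain >= 0


# ---------------------------------------------------------------------------
# relative importance
# ---------------------------------------------------------------------------

def _hand_built_forest():
    """One tree, wAcc 0.75: root splits on feature 1, its left child
    (10 of 20 samples) splits on feature 0 with IG 1.0 bit."""
    inner = TreeNode(
        n_samples=10, class_counts=np.array([5, 5]), prediction=0,
        feature=0, threshold=0, info_gain=1.0,
        left=TreeNode(5, np.array([5, 0]), 0),
        right=TreeNode(5, np.array([0, 5]), 1),
    )
    root = TreeNode(
        n_samples=20, class_counts=np.array([10, 10]), prediction=0,
        feature=1, threshold=1, info_gain=0.1,
        left=inner,
        right=TreeNode(10, np.array([5, 5]), 0),
    )
    tree = DecisionTree(root=root, n_root=20, n_classes=2, wacc=0.75)
    return Forest(trees=[tree], n_features=2, config=MCFSConfig(s=1, t=1))


def test_ri_of_direct_equation_evaluation():
    forest = _hand_built_forest()
    # 0.75^1 * 1.0 * (10/20)^1
    assert relative_importance(0, forest) == pytest.approx(0.375, abs=1e-12)


def test_ri_zero_for_absent_feature():
    forest = _hand_built_forest()
    assert relative_importance(7, forest, u=1, v=1) == 0.0


def test_ri_additive_over_duplicated_trees():
    forest = _hand_built_forest()
    doubled = Forest(
        trees=forest.trees * 2, n_features=2, config=forest.config
    )
    for f in range(2):
        assert relative_importance(f, doubled) == pytest.approx(
            2 * relative_importance(f, forest), abs=1e-12
        )


def test_ri_scores_agree_with_per_feature_oracle(two_class_cohort):
    matrix, _ = two_class_cohort
    config = MCFSConfig(s=10, m=8, t=2, u=1.5, v=0.7, seed=4)
    forest = build_forest(matrix, config)
    scores = ri_scores(forest)
    oracle = ri_oracle(forest, matrix.n_features, u=1.5, v=0.7)
    np.testing.assert_allclose(scores, oracle, atol=1e-12)
    for f in (0, 17, 55):
        assert relative_importance(f, forest) == pytest.approx(
            oracle[f], abs=1e-12
        )


def test_ri_conservation_partition_of_forest_total(two_class_cohort):
    matrix, _ = two_class_cohort
    forest = build_forest(matrix, MCFSConfig(s=20, m=10, t=3, seed=9))
    total_by_feature = ri_scores(forest).sum()
    total_by_tree = sum(
        tree.wacc * sum(
            node.info_gain * (node.n_samples / tree.n_root)
            for node in tree.internal_nodes()
        )
        for tree in forest.trees
    )
    assert total_by_feature == pytest.approx(total_by_tree, abs=1e-9)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def test_ranking_is_deterministic(two_class_cohort):
    matrix, _ = two_class_cohort
    config = MCFSConfig(s=15, m=10, t=2, seed=21)
    r1 = mcfs_rank(matrix, config)
    r2 = mcfs_rank(matrix, config)
    assert r1.feature_ids == r2.feature_ids
    assert np.array_equal(r1.scores, r2.scores)


def test_ranking_recovers_planted_features(two_class_cohort):
    matrix, planted = two_class_cohort
    ranked = mcfs_rank(matrix, MCFSConfig(s=60, m=15, t=3, seed=2))
    top = set(ranked.top(15))
    assert len(top & {p.feature_id for p in planted}) >= 8


def test_no_signal_null_gives_uniform_planted_ranks():
    spec = CohortSpec(
        n_per_class=(60, 60), n_features=100, n_informative_per_class=5,
        effect_strength=0.0, seed=0,
    )
    matrix, planted = generate_cohort(spec)
    ranked = mcfs_rank(matrix, MCFSConfig(s=60, m=10, t=2, seed=0))
    rank_of = {f: r for r, f in enumerate(ranked.feature_ids)}
    planted_ranks = [rank_of[p.feature_id] for p in planted]
    noise_ranks = [
        r for f, r in rank_of.items()
        if f not in {p.feature_id for p in planted}
    ]
    p_value = mannwhitneyu(planted_ranks, noise_ranks).pvalue
    assert p_value > 0.01


def test_per_feature_ri_invariant_under_column_permutation(two_class_cohort):
    from pancnv.matrix import CNVMatrix

    matrix, _ = two_class_cohort
    config = MCFSConfig(s=12, m=8, t=2, seed=6)
    subsets = draw_subsets(matrix.n_features, config)
    base = ri_scores(forest_from_subsets(matrix, subsets, config))

    rng = np.random.default_rng(99)
    perm = rng.permutation(matrix.n_features)  # new_col = position of old col
    inv = np.argsort(perm)
    permuted = CNVMatrix(
        values=matrix.values[:, perm],
        sample_ids=matrix.sample_ids,
        feature_ids=[matrix.feature_ids[j] for j in perm],
        labels=matrix.labels,
        class_names=matrix.class_names,
        state_values=matrix.state_values,
    )
    mapped_subsets = [inv[s] for s in subsets]
    scores = ri_scores(forest_from_subsets(permuted, mapped_subsets, config))
    np.testing.assert_allclose(scores, base[perm], atol=1e-12)


def test_m_larger_than_feature_count_rejected(two_class_cohort):
    matrix, _ = two_class_cohort
    with pytest.raises(MCFSConfigError, match="m="):
        mcfs_rank(matrix, MCFSConfig(s=2, m=1000, t=1))
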