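"""Monte Carlo Feature Selection (MCFS).

MCFS ranks features by aggregating their contribution over a large
ensemble of decision trees: ``s`` random subsets of ``m`` features are
drawn from the ``M`` original ones, and for each subset ``t`` trees are
grown on independent train/held-out splits of the samples, giving
``s*t`` trees in total.  Each feature ``f`` receives a relative
importance score

    RI_f = sum over trees tau of (wAcc_tau)^u *
           sum over nodes n_f(tau) splitting on f of
           IG(n_f(tau)) * (no. in n_f(tau) / no. in tau)^v

where ``wAcc`` is the tree's weighted (mean per-class recall) accuracy
on its held-out split, ``IG`` is the information gain of the node's
split in bits, and the fraction is the node's share of the tree's
training samples.  ``u`` and ``v`` are fixed real exponents (default 1).

Trees are grown top-down by greedy information-gain maximization using
binary threshold splits over the ordered discrete CNV states
(``state <= theta`` goes left), because copy-number states are ordinal
(loss < neutral < gain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from pancnv._seeds import derive_seed
from pancnv.io import RankedFeatures
from pancnv.matrix import CNVMatrix

#: splits with information gain below this are treated as no gain
_IG_TOL = 1e-12


class MCFSConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MCFSConfig:
    """MCFS run parameters.

    ``m=None`` resolves to ``max(5, ceil(0.05*M))``.  ``train_fraction``
    of each class is used to grow each tree; the remainder is the
    held-out split on which wAcc is measured.
    """

    s: int = 300
    m: int | None = None
    t: int = 5
    u: float = 1.0
    v: float = 1.0
    train_fraction: float = 2.0 / 3.0
    max_depth: int | None = None
    min_samples_split: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 1 or self.t < 1:
            raise MCFSConfigError("s and t must be >= 1")
        if self.m is not None and self.m < 1:
            raise MCFSConfigError("m must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise MCFSConfigError("train_fraction must lie in (0, 1)")
        if self.min_samples_split < 2:
            raise MCFSConfigError("min_samples_split must be >= 2")

    def resolved_m(self, n_features: int) -> int:
        if self.m is not None:
            if self.m > n_features:
                raise MCFSConfigError(
                    f"m={self.m} exceeds the {n_features} available features"
                )
            return self.m
        return min(n_features, max(5, math.ceil(0.05 * n_features)))


# ---------------------------------------------------------------------------
# elementary quantities
# ---------------------------------------------------------------------------

def entropy(class_counts) -> float:
    """Shannon entropy of a frequency table, in bits (0*log0 = 0)."""
    counts = np.asarray(class_counts, dtype=float)
    if counts.ndim != 1 or (counts < 0).any():
        raise ValueError("class_counts must be a 1-D non-negative vector")
    total = counts.sum()
    if total <= 0:
        raise ValueError("entropy of an empty frequency table is undefined")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(parent_counts, children_counts: Iterable) -> float:
    """Entropy(parent) minus the sample-weighted mean entropy of the children.

    The children must partition the parent's frequency table exactly.
    """
    parent = np.asarray(parent_counts, dtype=np.int64)
    children = [np.asarray(ch, dtype=np.int64) for ch in children_counts]
    if not children or any(ch.shape != parent.shape for ch in children):
        raise ValueError("children must share the parent's class dimension")
    if not np.array_equal(np.sum(children, axis=0), parent):
        raise ValueError("children counts do not sum to the parent's")
    n = parent.sum()
    cond = sum(
        (ch.sum() / n) * entropy(ch) for ch in children if ch.sum() > 0
    )
    return entropy(parent) - cond


def weighted_accuracy(confusion) -> float:
    """Mean per-class recall of a confusion matrix (rows = true class)."""
    conf = np.asarray(confusion, dtype=float)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    row_sums = conf.sum(axis=1)
    if (row_sums == 0).any():
        k = int(np.flatnonzero(row_sums == 0)[0])
        raise ValueError(f"class {k} has zero true samples; wAcc undefined")
    return float(np.mean(np.diag(conf) / row_sums))


def _entropy_rows(counts: np.ndarray) -> np.ndarray:
    """Entropy along the last axis; zero-total rows give 0."""
    total = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / total
        terms = np.where(counts > 0, p * np.log2(p), 0.0)
    h = -terms.sum(axis=-1)
    return np.where(total[..., 0] > 0, h, 0.0)


# ---------------------------------------------------------------------------
# decision trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    n_samples: int
    class_counts: np.ndarray
    prediction: int
    feature: int | None = None   # global feature index of the split
    threshold: int | None = None  # state index; state <= threshold goes left
    info_gain: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class DecisionTree:
    """Greedy information-gain tree with per-node IG and sample counts."""

    root: TreeNode
    n_root: int
    n_classes: int
    wacc: float | None = None

    def internal_nodes(self) -> Iterable[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                yield node
                stack.append(node.left)
                stack.append(node.right)


def _best_split(X: np.ndarray, y: np.ndarray, n_classes: int, n_states: int):
    """Best (local feature, threshold, IG) over all binary ordinal splits.

    Ties are broken toward the smallest local feature index, then the
    smallest threshold (the order scanned by argmax).
    """
    n, m = X.shape
    flat = (np.arange(m)[None, :] * n_states + X) * n_classes + y[:, None]
    counts = np.bincount(
        flat.ravel(), minlength=m * n_states * n_classes
    ).reshape(m, n_states, n_classes).astype(float)
    parent = np.bincount(y, minlength=n_classes).astype(float)

    cum = counts.cumsum(axis=1)
    left = cum[:, :-1, :]                    # (m, S-1, c)
    right = parent[None, None, :] - left
    n_left = left.sum(axis=-1)
    n_right = right.sum(axis=-1)
    cond = (n_left * _entropy_rows(left) + n_right * _entropy_rows(right)) / n
    ig = entropy(parent) - cond
    ig[(n_left == 0) | (n_right == 0)] = -np.inf

    k = int(np.argmax(ig))
    j, thr = divmod(k, n_states - 1)
    return j, thr, float(ig[j, thr])


def build_tree(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    n_states: int,
    config: MCFSConfig | None = None,
    feature_indices: np.ndarray | None = None,
) -> DecisionTree:
    """Grow a decision tree on training data restricted to a feature subset.

    ``X`` holds ordinal state indices in ``[0, n_states)`` for the subset
    columns; ``feature_indices`` maps those columns to global feature
    indices recorded at the nodes (identity when omitted).  Degenerate
    input (single class or no positive-gain split) yields a leaf-only
    tree predicting the majority class.
    """
    config = config or MCFSConfig()
    X = np.asarray(X)
    y = np.asarray(y)
    if feature_indices is None:
        feature_indices = np.arange(X.shape[1])

    def make_node(rows: np.ndarray, depth: int) -> TreeNode:
        counts = np.bincount(y[rows], minlength=n_classes)
        node = TreeNode(
            n_samples=rows.size,
            class_counts=counts,
            prediction=int(np.argmax(counts)),
        )
        pure = np.count_nonzero(counts) <= 1
        if (
            pure
            or rows.size < config.min_samples_split
            or (config.max_depth is not None and depth >= config.max_depth)
        ):
            return node
        j, thr, ig = _best_split(X[rows], y[rows], n_classes, n_states)
        if ig <= _IG_TOL:
            return node
        go_left = X[rows, j] <= thr
        node.feature = int(feature_indices[j])
        node.threshold = int(thr)
        node.info_gain = ig
        node.left = make_node(rows[go_left], depth + 1)
        node.right = make_node(rows[~go_left], depth + 1)
        return node

    root = make_node(np.arange(X.shape[0]), 0)
    return DecisionTree(root=root, n_root=X.shape[0], n_classes=n_classes)


def predict_tree(tree: DecisionTree, X: np.ndarray) -> np.ndarray:
    """Predict class indices; ``X`` columns are indexed by the global
    feature indices stored at the nodes."""
    out = np.empty(X.shape[0], dtype=np.int64)

    def walk(node: TreeNode, rows: np.ndarray) -> None:
        if node.is_leaf or rows.size == 0:
            out[rows] = node.prediction
            return
        go_left = X[rows, node.feature] <= node.threshold
        walk(node.left, rows[go_left])
        walk(node.right, rows[~go_left])

    walk(tree.root, np.arange(X.shape[0]))
    return out


# ---------------------------------------------------------------------------
# forest and relative importance
# ---------------------------------------------------------------------------

@dataclass
class Forest:
    trees: list[DecisionTree]
    n_features: int
    config: MCFSConfig


def _stratified_split(y: np.ndarray, train_fraction: float, rng: np.random.Generator):
    train, test = [], []
    for k in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == k))
        if idx.size < 2:
            raise MCFSConfigError(
                f"class {k} has {idx.size} sample(s); need >= 2 to split"
            )
        n_tr = int(np.clip(round(train_fraction * idx.size), 1, idx.size - 1))
        train.append(idx[:n_tr])
        test.append(idx[n_tr:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def draw_subsets(n_features: int, config: MCFSConfig) -> list[np.ndarray]:
    """The ``s`` seeded random feature subsets of size ``m``."""
    m = config.resolved_m(n_features)
    rng = np.random.default_rng(derive_seed(config.seed, "subsets"))
    return [
        np.sort(rng.choice(n_features, size=m, replace=False))
        for _ in range(config.s)
    ]


def forest_from_subsets(
    matrix: CNVMatrix, subsets: list[np.ndarray], config: MCFSConfig
) -> Forest:
    """Grow ``t`` trees per feature subset on independent stratified
    train/held-out sample splits and score each tree's held-out wAcc.

    Sample splits are seeded per (subset, tree) from the config seed, so
    the forest depends on the subsets only through their contents.
    """
    X = matrix.state_indices()
    y = matrix.labels
    c = matrix.n_classes
    S = len(matrix.state_values)
    trees: list[DecisionTree] = []
    for si, subset in enumerate(subsets):
        subset = np.asarray(subset)
        for ti in range(config.t):
            rng = np.random.default_rng(derive_seed(config.seed, "split", si, ti))
            train, test = _stratified_split(y, config.train_fraction, rng)
            tree = build_tree(
                X[np.ix_(train, subset)],
                y[train],
                n_classes=c,
                n_states=S,
                config=config,
                feature_indices=subset,
            )
            pred = predict_tree(tree, X[test])
            conf = np.bincount(
                y[test] * c + pred, minlength=c * c
            ).reshape(c, c)
            tree.wacc = weighted_accuracy(conf)
            trees.append(tree)
    return Forest(trees=trees, n_features=matrix.n_features, config=config)


def build_forest(matrix: CNVMatrix, config: MCFSConfig) -> Forest:
    subsets = draw_subsets(matrix.n_features, config)
    return forest_from_subsets(matrix, subsets, config)


def ri_scores(
    forest: Forest, n_features: int | None = None,
    u: float | None = None, v: float | None = None,
) -> np.ndarray:
    """Relative importance of every feature, aggregated over the forest."""
    n_features = forest.n_features if n_features is None else n_features
    u = forest.config.u if u is None else u
    v = forest.config.v if v is None else v
    ri = np.zeros(n_features)
    for tree in forest.trees:
        w = tree.wacc ** u
        for node in tree.internal_nodes():
            ri[node.feature] += (
                w * node.info_gain * (node.n_samples / tree.n_root) ** v
            )
    return ri


def relative_importance(
    feature: int, forest: Forest, u: float | None = None, v: float | None = None
) -> float:
    """RI of a single feature (0 if it splits no node in the forest)."""
    u = forest.config.u if u is None else u
    v = forest.config.v if v is None else v
    total = 0.0
    for tree in forest.trees:
        w = tree.wacc ** u
        for node in tree.internal_nodes():
            if node.feature == feature:
                total += (
                    w * node.info_gain * (node.n_samples / tree.n_root) ** v
                )
    return total


def mcfs_rank(matrix: CNVMatrix, config: MCFSConfig) -> RankedFeatures:
    """Full MCFS ranking: all features sorted by RI descending, ties
    broken lexicographically by feature ID."""
    forest = build_forest(matrix, config)
    scores = ri_scores(forest)
    return RankedFeatures.from_scores(matrix.feature_ids, scores)
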