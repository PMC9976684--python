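"""Deterministic best-first CART with a terminal-node cap.

Greedy binary splits minimize weighted Gini impurity over all (feature,
midpoint threshold) pairs. Growth proceeds best-first (largest impurity
decrease next) until the terminal-node cap is reached, leaves are pure, or
the minimum leaf size blocks further splits. All ties break deterministically:
within a node, the lower feature index then the lower threshold wins; between
nodes with equal impurity decrease, the earlier-created node splits first.
The cap (not cost-complexity pruning) is the capacity control.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted


def gini(counts: np.ndarray) -> float:
    """Gini impurity of a class-count vector."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p**2).sum())


@dataclass
class TreeNode:
    node_id: int
    depth: int
    counts: np.ndarray
    impurity: float
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    @property
    def prediction(self) -> int:
        return int(np.argmax(self.counts))  # lowest class index wins ties


def _best_split(
    X: np.ndarray, y_idx: np.ndarray, rows: np.ndarray,
    n_classes: int, min_leaf: int,
) -> tuple[float, int, float, np.ndarray] | None:
    """Best (decrease, feature, threshold, left-mask) for one node, or None.

    The decrease is the unnormalized weighted impurity drop
    ``n*g - n_l*g_l - n_r*g_r``; deterministic tie-break on lower feature
    index then lower threshold.
    """
    y_node = y_idx[rows]
    n = len(y_node)
    counts = np.bincount(y_node, minlength=n_classes).astype(float)
    g_parent = gini(counts)
    if g_parent == 0.0 or n < 2 * min_leaf:
        return None
    best: tuple[float, int, float] | None = None
    for j in range(X.shape[1]):
        xj = X[rows, j]
        order = np.argsort(xj, kind="mergesort")
        xs, ys = xj[order], y_node[order]
        if xs[0] == xs[-1]:
            continue  # constant feature in this node
        left_counts = np.zeros(n_classes)
        for i in range(n - 1):
            left_counts[ys[i]] += 1
            if xs[i] == xs[i + 1]:
                continue
            n_l = i + 1
            n_r = n - n_l
            if n_l < min_leaf or n_r < min_leaf:
                continue
            right_counts = counts - left_counts
            decrease = n * g_parent - n_l * gini(left_counts) - n_r * gini(right_counts)
            thr = (xs[i] + xs[i + 1]) / 2.0
            if decrease > 1e-12 and (
                best is None
                or decrease > best[0] + 1e-12
                or (abs(decrease - best[0]) <= 1e-12 and (j, thr) < (best[1], best[2]))
            ):
                best = (decrease, j, thr)
    if best is None:
        return None
    decrease, j, thr = best
    left_mask = rows.copy()
    left_mask[rows] = X[rows, j] <= thr
    return decrease, j, thr, left_mask


class GiniTreeClassifier(BaseEstimator, ClassifierMixin):
    """CART classifier with deterministic growth and a leaf cap.

    Parameters
    ----------
    max_leaf_nodes : int, default 6
        Terminal-node cap; growth is best-first so a larger cap extends the
        smaller tree (training accuracy is non-decreasing in the cap).
    min_samples_leaf : int, default 2
        Each child of a split must keep at least this many samples.
    """

    def __init__(self, max_leaf_nodes: int = 6, min_samples_leaf: int = 2):
        self.max_leaf_nodes = max_leaf_nodes
        self.min_samples_leaf = min_samples_leaf

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n_samples, n_features) matching y")
        if np.isnan(X).any():
            raise ValueError("X contains missing values; impute before fitting")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        if self.max_leaf_nodes < 2:
            raise ValueError("max_leaf_nodes must be >= 2")
        class_idx = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([class_idx[v] for v in y])
        n_classes = len(self.classes_)
        self.feature_names_ = (
            list(feature_names) if feature_names is not None
            else [f"x{j}" for j in range(X.shape[1])]
        )
        if len(self.feature_names_) != X.shape[1]:
            raise ValueError("feature_names length mismatch")

        self._next_id = 0

        def new_node(rows: np.ndarray, depth: int) -> TreeNode:
            counts = np.bincount(y_idx[rows], minlength=n_classes).astype(float)
            node = TreeNode(self._next_id, depth, counts, gini(counts))
            self._next_id += 1
            return node

        root_rows = np.ones(len(y), dtype=bool)
        self.root_ = new_node(root_rows, 0)
        # heap of (-decrease, node_id) with split details stored alongside
        heap: list[tuple[float, int]] = []
        pending: dict[int, tuple[TreeNode, np.ndarray, tuple]] = {}

        def consider(node: TreeNode, rows: np.ndarray) -> None:
            found = _best_split(X, y_idx, rows, n_classes, self.min_samples_leaf)
            if found is not None:
                decrease = found[0]
                heapq.heappush(heap, (-decrease, node.node_id))
                pending[node.node_id] = (node, rows, found)

        consider(self.root_, root_rows)
        n_leaves = 1
        while heap and n_leaves < self.max_leaf_nodes:
            _, node_id = heapq.heappop(heap)
            node, rows, (decrease, j, thr, left_mask) = pending.pop(node_id)
            node.feature = j
            node.threshold = thr
            right_mask = rows & ~left_mask
            node.left = new_node(left_mask, node.depth + 1)
            node.right = new_node(right_mask, node.depth + 1)
            n_leaves += 1
            consider(node.left, left_mask)
            consider(node.right, right_mask)
        self.n_leaves_ = n_leaves
        return self

    # -- traversal -----------------------------------------------------------
    def _route(self, x: np.ndarray) -> TreeNode:
        node = self.root_
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node

    def apply(self, X) -> np.ndarray:
        """Terminal-node id for each sample."""
        check_is_fitted(self, "root_")
        X = np.asarray(X, dtype=float)
        return np.array([self._route(x).node_id for x in X])

    def predict(self, X):
        check_is_fitted(self, "root_")
        X = np.asarray(X, dtype=float)
        return np.array([self.classes_[self._route(x).prediction] for x in X])

    def predict_proba(self, X) -> np.ndarray:
        """Terminal-node class proportions."""
        check_is_fitted(self, "root_")
        X = np.asarray(X, dtype=float)
        out = np.zeros((len(X), len(self.classes_)))
        for i, x in enumerate(X):
            leaf = self._route(x)
            out[i] = leaf.counts / leaf.counts.sum()
        return out

    # -- introspection ---------------------------------------------------------
    def split_features(self) -> list[int]:
        """Distinct split-feature indices in breadth-first (shallowest) order."""
        check_is_fitted(self, "root_")
        seen: list[int] = []
        queue = [self.root_]
        while queue:
            node = queue.pop(0)
            if node.is_leaf:
                continue
            if node.feature not in seen:
                seen.append(node.feature)
            queue.extend([node.left, node.right])
        return seen

    def to_dict(self) -> dict[str, Any]:
        """Serialize the tree as nested nodes (JSON-friendly)."""
        check_is_fitted(self, "root_")

        def conv(node: TreeNode) -> dict[str, Any]:
            d: dict[str, Any] = {
                "counts": {str(c): int(v) for c, v in zip(self.classes_, node.counts)},
                "impurity": round(node.impurity, 12),
            }
            if node.is_leaf:
                d["prediction"] = str(self.classes_[node.prediction])
            else:
                d["feature"] = self.feature_names_[node.feature]
                d["threshold"] = float(node.threshold)
                d["left"] = conv(node.left)
                d["right"] = conv(node.right)
            return d

        return conv(self.root_)
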