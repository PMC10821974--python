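"""Minimal reference implementation of the randomized-tree-ensemble contract.

The classification track relies on a bagged ensemble of randomized decision
trees that (a) yields class-probability estimates by averaging per-tree leaf
frequencies and (b) exposes impurity-decrease feature importances normalized
to sum to one. The production path is backed by scikit-learn; this module is
a small, fully transparent implementation of the same contract, kept for
contract tests and for readers who want the algorithm in plain numpy. It is
not tuned for speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class _Node:
    feature: int = -1          # -1 marks a leaf
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    value: float = 0.0         # leaf: fraction of positives


def _gini(pos: int, n: int) -> float:
    if n == 0:
        return 0.0
    p = pos / n
    return 2.0 * p * (1.0 - p)


class ReferenceRandomForest:
    """Bootstrap-aggregated CART trees with per-split feature subsampling.

    Mirrors the subset of the scikit-learn estimator API the pipeline uses:
    ``fit``, ``predict_proba`` (column 1 = positive class) and
    ``feature_importances_`` (impurity decrease, normalized to sum to 1).
    Labels must be 0/1.
    """

    def __init__(
        self,
        n_estimators: int = 50,
        max_depth: int | None = None,
        max_features: str | float = "sqrt",
        min_samples_leaf: int = 1,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def _n_features_split(self, p: int) -> int:
        mf = self.max_features
        if mf == "sqrt":
            return max(1, int(math.sqrt(p)))
        if mf == "log2":
            return max(1, int(math.log2(p))) if p > 1 else 1
        if isinstance(mf, float):
            return max(1, int(round(mf * p)))
        raise ValueError(f"unsupported max_features {mf!r}")

    def _build(self, X, y, depth, rng, importances):
        n = len(y)
        pos = int(y.sum())
        node = _Node(value=pos / n)
        impurity = _gini(pos, n)
        if (
            impurity == 0.0
            or n < 2 * self.min_samples_leaf
            or (self.max_depth is not None and depth >= self.max_depth)
        ):
            return node
        m = self._n_features_split(X.shape[1])
        feats = rng.choice(X.shape[1], size=m, replace=False)
        best = None  # (gain, feature, threshold, mask)
        for f in feats:
            col = X[:, f]
            order = np.argsort(col, kind="mergesort")
            cs, ys = col[order], y[order]
            cum_pos = np.cumsum(ys)
            for i in range(self.min_samples_leaf, n - self.min_samples_leaf + 1):
                if i < n and cs[i - 1] == cs[i]:
                    continue  # cannot split between equal values
                if i >= n:
                    break
                nl, nr = i, n - i
                pl = int(cum_pos[i - 1])
                gain = impurity - (
                    nl / n * _gini(pl, nl) + nr / n * _gini(pos - pl, nr)
                )
                if gain > 1e-12 and (best is None or gain > best[0]):
                    thr = 0.5 * (cs[i - 1] + cs[i])
                    best = (gain, int(f), thr, col <= thr)
        if best is None:
            return node
        gain, f, thr, mask = best
        importances[f] += n * gain
        node.feature, node.threshold = f, thr
        node.left = self._build(X[mask], y[mask], depth + 1, rng, importances)
        node.right = self._build(X[~mask], y[~mask], depth + 1, rng, importances)
        return node

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.random_state)
        n, p = X.shape
        self._trees: list[_Node] = []
        raw_imp = np.zeros(p)
        for _ in range(self.n_estimators):
            idx = rng.integers(0, n, size=n)  # bootstrap
            tree_imp = np.zeros(p)
            self._trees.append(self._build(X[idx], y[idx], 0, rng, tree_imp))
            s = tree_imp.sum()
            if s > 0:
                raw_imp += tree_imp / s
        s = raw_imp.sum()
        self.feature_importances_ = raw_imp / s if s > 0 else raw_imp
        self.classes_ = np.array([0, 1])
        return self

    @staticmethod
    def _predict_one(node: _Node, row) -> float:
        while node.feature != -1:
            node = node.left if row[node.feature] <= node.threshold else node.right
        return node.value

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        probs = np.zeros(len(X))
        for tree in self._trees:
            probs += [self._predict_one(tree, row) for row in X]
        probs /= len(self._trees)
        return np.column_stack([1.0 - probs, probs])
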