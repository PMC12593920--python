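"""Exact Shapley attributions for decision-tree ensembles.

Path-dependent TreeSHAP: for each tree, feature coalitions are propagated
down the tree in a single traversal, splitting cover (training-sample
weight) between branches when a coalition excludes the split feature.  The
per-tree attributions are averaged over a forest, matching how a random
forest averages per-tree class probabilities, so local accuracy holds on
the probability scale: base value + attribution row sum = predicted
probability for every sample.

Complexity is O(leaves x depth^2) per sample per tree.
"""

from __future__ import annotations

import numpy as np


class _Path:
    """Unique decision path: parallel arrays of feature index, zero/one
    fractions and Shapley path weights."""

    __slots__ = ("d", "z", "o", "w")

    def __init__(self, capacity: int):
        self.d = np.full(capacity, -1, dtype=np.int64)
        self.z = np.zeros(capacity)
        self.o = np.zeros(capacity)
        self.w = np.zeros(capacity)

    def copy(self) -> "_Path":
        p = _Path(self.d.size)
        p.d[...] = self.d
        p.z[...] = self.z
        p.o[...] = self.o
        p.w[...] = self.w
        return p


def _extend(m: _Path, depth: int, pz: float, po: float, pi: int) -> None:
    m.d[depth], m.z[depth], m.o[depth] = pi, pz, po
    m.w[depth] = 1.0 if depth == 0 else 0.0
    for i in range(depth - 1, -1, -1):
        m.w[i + 1] += po * m.w[i] * (i + 1) / (depth + 1)
        m.w[i] = pz * m.w[i] * (depth - i) / (depth + 1)


def _unwind(m: _Path, depth: int, idx: int) -> None:
    one = m.o[idx]
    zero = m.z[idx]
    nxt = m.w[depth]
    for i in range(depth - 1, -1, -1):
        if one != 0:
            tmp = m.w[i]
            m.w[i] = nxt * (depth + 1) / ((i + 1) * one)
            nxt = tmp - m.w[i] * zero * (depth - i) / (depth + 1)
        else:
            m.w[i] = m.w[i] * (depth + 1) / (zero * (depth - i))
    for i in range(idx, depth):
        m.d[i], m.z[i], m.o[i] = m.d[i + 1], m.z[i + 1], m.o[i + 1]


def _unwound_sum(m: _Path, depth: int, idx: int) -> float:
    one = m.o[idx]
    zero = m.z[idx]
    nxt = m.w[depth]
    total = 0.0
    if one != 0:
        for i in range(depth - 1, -1, -1):
            tmp = nxt / ((i + 1) * one)
            total += tmp
            nxt = m.w[i] - tmp * zero * (depth - i)
    else:
        for i in range(depth - 1, -1, -1):
            total += m.w[i] / (zero * (depth - i))
    return total * (depth + 1)


class TreeArrays:
    """Flat arrays for a single decision tree with scalar leaf values."""

    def __init__(self, children_left, children_right, feature, threshold,
                 value, node_weight):
        self.left = np.asarray(children_left, dtype=np.int64)
        self.right = np.asarray(children_right, dtype=np.int64)
        self.feature = np.asarray(feature, dtype=np.int64)
        self.threshold = np.asarray(threshold, dtype=float)
        self.value = np.asarray(value, dtype=float)
        self.weight = np.asarray(node_weight, dtype=float)
        self.max_depth = self._depth(0) + 2

    def _depth(self, node: int) -> int:
        if self.left[node] < 0:
            return 0
        return 1 + max(self._depth(self.left[node]), self._depth(self.right[node]))

    @classmethod
    def from_sklearn(cls, estimator, class_index: int = 1) -> "TreeArrays":
        """Wrap a fitted sklearn tree; leaf value = probability of
        ``class_index`` (row-normalized node value), matching
        ``predict_proba``."""
        t = estimator.tree_
        raw = t.value[:, 0, :]
        # node values may already be normalized (sklearn >= 1.3 stores
        # per-node class fractions); normalize defensively either way
        prob = raw / np.clip(raw.sum(axis=1, keepdims=True), 1e-300, None)
        return cls(t.children_left, t.children_right, t.feature, t.threshold,
                   prob[:, class_index], t.weighted_n_node_samples)

    def predict_one(self, x: np.ndarray) -> float:
        node = 0
        while self.left[node] >= 0:
            node = (self.left[node] if x[self.feature[node]] <= self.threshold[node]
                    else self.right[node])
        return float(self.value[node])

    def expected_value(self) -> float:
        """Cover-weighted mean leaf value (the TreeSHAP base value)."""
        def rec(node: int) -> float:
            if self.left[node] < 0:
                return float(self.value[node])
            wl = self.weight[self.left[node]]
            wr = self.weight[self.right[node]]
            return (wl * rec(self.left[node]) + wr * rec(self.right[node])) / (wl + wr)
        return rec(0)


def tree_shap_values(tree: TreeArrays, x: np.ndarray, n_features: int) -> np.ndarray:
    """Shapley attributions for one sample on one tree."""
    phi = np.zeros(n_features)

    def recurse(node: int, m: _Path, depth: int, pz: float, po: float, pi: int):
        m = m.copy()
        _extend(m, depth, pz, po, pi)
        if tree.left[node] < 0:
            leaf = tree.value[node]
            for i in range(1, depth + 1):
                w = _unwound_sum(m, depth, i)
                phi[m.d[i]] += w * (m.o[i] - m.z[i]) * leaf
            return
        feat = tree.feature[node]
        if x[feat] <= tree.threshold[node]:
            hot, cold = tree.left[node], tree.right[node]
        else:
            hot, cold = tree.right[node], tree.left[node]
        w = tree.weight[node]
        hot_z = tree.weight[hot] / w
        cold_z = tree.weight[cold] / w
        inc_z = inc_o = 1.0
        path_idx = 0
        for i in range(1, depth + 1):
            if m.d[i] == feat:
                path_idx = i
                break
        if path_idx > 0:
            inc_z, inc_o = m.z[path_idx], m.o[path_idx]
            _unwind(m, depth, path_idx)
            depth -= 1
        recurse(hot, m, depth + 1, hot_z * inc_z, inc_o, feat)
        recurse(cold, m, depth + 1, cold_z * inc_z, 0.0, feat)

    recurse(0, _Path(tree.max_depth + 2), 0, 1.0, 1.0, -1)
    return phi


def forest_shap(forest, X: np.ndarray, class_index: int = 1
                ) -> tuple[np.ndarray, float]:
    """(attributions, base value) for a fitted sklearn forest.

    Attributions are on the probability scale for ``class_index`` and
    average the per-tree TreeSHAP values, so for each row
    ``base + phi.sum()`` equals ``predict_proba[:, class_index]``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    trees = [TreeArrays.from_sklearn(e, class_index) for e in forest.estimators_]
    phi = np.zeros((n, p))
    for t in trees:
        for i in range(n):
            phi[i] += tree_shap_values(t, X[i], p)
    phi /= len(trees)
    base = float(np.mean([t.expected_value() for t in trees]))
    return phi, base
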