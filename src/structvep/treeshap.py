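"""Exact Shapley attributions for tree ensembles.

Implements the path-dependent Tree SHAP recursion: for each decision path the
polynomial of subset weights is carried along (EXTEND/UNWIND) so each
feature's exact Shapley value under the tree's own cover-conditioned
expectation is obtained in O(leaves * depth^2) per example.  The conditional
expectation v(S) splits un-fixed features over children in proportion to
training cover, which makes the base value the cover-weighted mean leaf value
and guarantees the local-accuracy identity

    base_value + sum_i phi_i == f(x)          (per example, exactly)

``brute_force_shap`` recomputes the same quantity by explicit enumeration of
feature subsets; it is exponential in the number of distinct features of the
tree and exists as an independent oracle for small trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np


@dataclass
class TreeArrays:
    """Flat arrays describing one regression tree (sklearn layout)."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray  # split feature per node; arbitrary at leaves
    threshold: np.ndarray
    value: np.ndarray  # scalar output per node (used at leaves)
    cover: np.ndarray  # weighted training-sample count per node

    def is_leaf(self, node: int) -> bool:
        return self.children_left[node] < 0


def _from_sklearn_tree(tree, class_index: int = 1) -> TreeArrays:
    t = tree.tree_
    value = t.value.reshape(t.node_count, -1)
    if value.shape[1] > 1:  # classifier: per-node class distribution
        prob = value / value.sum(axis=1, keepdims=True)
        out = prob[:, class_index]
    else:
        out = value[:, 0]
    return TreeArrays(
        children_left=t.children_left,
        children_right=t.children_right,
        feature=t.feature,
        threshold=t.threshold,
        value=out.astype(float),
        cover=t.weighted_n_node_samples.astype(float),
    )


def tree_expected_value(tree: TreeArrays, node: int = 0) -> float:
    """Cover-weighted mean leaf value (the conditional expectation of the
    empty feature set)."""
    if tree.is_leaf(node):
        return float(tree.value[node])
    l, r = tree.children_left[node], tree.children_right[node]
    wl = tree.cover[l] / tree.cover[node]
    wr = tree.cover[r] / tree.cover[node]
    return wl * tree_expected_value(tree, l) + wr * tree_expected_value(tree, r)


# --- path-dependent Tree SHAP recursion -----------------------------------


class _Path:
    __slots__ = ("d", "z", "o", "w")

    def __init__(self, depth: int):
        self.d = np.full(depth, -1, dtype=np.int64)  # feature of each path element
        self.z = np.zeros(depth)  # fraction of zero (not-fixed) paths
        self.o = np.zeros(depth)  # fraction of one (fixed) paths
        self.w = np.zeros(depth)  # subset weight polynomial

    def copy(self, length: int) -> "_Path":
        p = _Path(len(self.d))
        p.d[:length] = self.d[:length]
        p.z[:length] = self.z[:length]
        p.o[:length] = self.o[:length]
        p.w[:length] = self.w[:length]
        return p


def _extend(p: _Path, depth: int, pz: float, po: float, pi: int) -> None:
    p.d[depth] = pi
    p.z[depth] = pz
    p.o[depth] = po
    p.w[depth] = 1.0 if depth == 0 else 0.0
    for i in range(depth - 1, -1, -1):
        p.w[i + 1] += po * p.w[i] * (i + 1) / (depth + 1)
        p.w[i] = pz * p.w[i] * (depth - i) / (depth + 1)


def _unwind(p: _Path, depth: int, i: int) -> None:
    one, zero = p.o[i], p.z[i]
    n = p.w[depth]
    for j in range(depth - 1, -1, -1):
        if one != 0.0:
            t = p.w[j]
            p.w[j] = n * (depth + 1) / ((j + 1) * one)
            n = t - p.w[j] * zero * (depth - j) / (depth + 1)
        else:
            p.w[j] = p.w[j] * (depth + 1) / (zero * (depth - j))
    for j in range(i, depth):
        p.d[j] = p.d[j + 1]
        p.z[j] = p.z[j + 1]
        p.o[j] = p.o[j + 1]


def _unwound_sum(p: _Path, depth: int, i: int) -> float:
    one, zero = p.o[i], p.z[i]
    total = 0.0
    if one != 0.0:
        n = p.w[depth]
        for j in range(depth - 1, -1, -1):
            t = n * (depth + 1) / ((j + 1) * one)
            total += t
            n = p.w[j] - t * zero * (depth - j) / (depth + 1)
    else:
        for j in range(depth - 1, -1, -1):
            total += p.w[j] * (depth + 1) / (zero * (depth - j))
    return total


def _max_path_depth(tree: TreeArrays) -> int:
    def depth(node: int) -> int:
        if tree.is_leaf(node):
            return 1
        return 1 + max(depth(tree.children_left[node]), depth(tree.children_right[node]))

    return depth(0)


def tree_shap_single(tree: TreeArrays, x: np.ndarray, n_features: int) -> np.ndarray:
    """Exact Shapley values of one tree for one example."""
    phi = np.zeros(n_features)
    maxd = _max_path_depth(tree) + 2

    def recurse(node: int, path: _Path, depth: int, pz: float, po: float, pi: int):
        path = path.copy(depth)
        _extend(path, depth, pz, po, pi)
        depth += 1
        if tree.is_leaf(node):
            for i in range(1, depth):
                w = _unwound_sum(path, depth - 1, i)
                phi[path.d[i]] += w * (path.o[i] - path.z[i]) * tree.value[node]
            return
        f = tree.feature[node]
        hot, cold = (
            (tree.children_left[node], tree.children_right[node])
            if x[f] <= tree.threshold[node]
            else (tree.children_right[node], tree.children_left[node])
        )
        iz = io = 1.0
        k = -1
        for i in range(1, depth):
            if path.d[i] == f:
                k = i
                break
        if k >= 0:
            iz, io = path.z[k], path.o[k]
            _unwind(path, depth - 1, k)
            depth -= 1
        cover = tree.cover[node]
        recurse(hot, path, depth, iz * tree.cover[hot] / cover, io, f)
        recurse(cold, path, depth, iz * tree.cover[cold] / cover, 0.0, f)

    recurse(0, _Path(maxd), 0, 1.0, 1.0, -1)
    return phi


# --- brute-force oracle ----------------------------------------------------


def _expvalue(tree: TreeArrays, x: np.ndarray, fixed: frozenset, node: int = 0) -> float:
    """Conditional expectation with the features in ``fixed`` set to x and the
    rest marginalized over training cover."""
    if tree.is_leaf(node):
        return float(tree.value[node])
    f = tree.feature[node]
    l, r = tree.children_left[node], tree.children_right[node]
    if f in fixed:
        child = l if x[f] <= tree.threshold[node] else r
        return _expvalue(tree, x, fixed, child)
    wl = tree.cover[l] / tree.cover[node]
    wr = tree.cover[r] / tree.cover[node]
    return wl * _expvalue(tree, x, fixed, l) + wr * _expvalue(tree, x, fixed, r)


def brute_force_shap(tree: TreeArrays, x: np.ndarray, n_features: int) -> np.ndarray:
    """Shapley values by explicit subset enumeration (oracle for small trees)."""
    used = sorted(
        {int(f) for f, l in zip(tree.feature, tree.children_left) if l >= 0}
    )
    m = len(used)
    phi = np.zeros(n_features)
    for i in used:
        others = [f for f in used if f != i]
        for k in range(m):
            for subset in combinations(others, k):
                s = frozenset(subset)
                weight = math.factorial(k) * math.factorial(m - k - 1) / math.factorial(m)
                phi[i] += weight * (
                    _expvalue(tree, x, s | {i}) - _expvalue(tree, x, s)
                )
    return phi


# --- ensemble-level API ----------------------------------------------------


def forest_shap_values(forest, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley values for a fitted sklearn RandomForestClassifier (probability
    of the positive class).  Returns ``(phi, base)`` with ``phi`` of shape
    (n_samples, n_features); ``base + phi.sum(1)`` equals ``predict_proba[:, 1]``.
    """
    X = np.asarray(X, dtype=float)
    trees = [_from_sklearn_tree(est) for est in forest.estimators_]
    n, m = X.shape
    phi = np.zeros((n, m))
    base = 0.0
    for tree in trees:
        base += tree_expected_value(tree)
        for i in range(n):
            phi[i] += tree_shap_single(tree, X[i], m)
    k = len(trees)
    return phi / k, base / k
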