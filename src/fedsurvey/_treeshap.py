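"""Exact path-dependent Shapley values for decision-tree ensembles.

Implements the polynomial-time tree-traversal algorithm for Shapley values of
a single decision tree, where absent features are marginalized using the
tree's own training cover (the weighted sample counts stored at every node).
The algorithm keeps, along the current root-to-node path, the subset-size
weights of all feature subsets simultaneously ("path weights"), extending the
path at each split and unwinding it when a feature repeats, so each leaf
contributes to every feature on its path in time O(depth²) instead of 2^M.

For an ensemble, per-feature values are the sum over trees (tree ensembles
predict by averaging, so callers divide by the tree count).  The per-sample
values satisfy local accuracy exactly: Σⱼ φⱼ(x) + E[f] = f(x), with
E[f] the cover-weighted mean prediction (the root node's stored value).

Functions are compiled with numba when available and fall back to pure
Python otherwise.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


__all__ = ["tree_shap_values", "expected_value"]


@njit(cache=False)
def _unwound_path_sum(zf, of, pw, unique_depth, path_index):
    one_fraction = of[path_index]
    zero_fraction = zf[path_index]
    next_one_portion = pw[unique_depth]
    total = 0.0
    if one_fraction != 0.0:
        for i in range(unique_depth - 1, -1, -1):
            tmp = next_one_portion * (unique_depth + 1) / ((i + 1) * one_fraction)
            total += tmp
            next_one_portion = pw[i] - tmp * zero_fraction * ((unique_depth - i) / (unique_depth + 1.0))
    else:
        for i in range(unique_depth - 1, -1, -1):
            total += pw[i] / (zero_fraction * ((unique_depth - i) / (unique_depth + 1.0)))
    return total


@njit(cache=False)
def _unwind_path(fi, zf, of, pw, unique_depth, path_index):
    one_fraction = of[path_index]
    zero_fraction = zf[path_index]
    next_one_portion = pw[unique_depth]
    for i in range(unique_depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = pw[i]
            pw[i] = next_one_portion * (unique_depth + 1) / ((i + 1) * one_fraction)
            next_one_portion = tmp - pw[i] * zero_fraction * (unique_depth - i) / (unique_depth + 1.0)
        else:
            pw[i] = pw[i] * (unique_depth + 1) / (zero_fraction * (unique_depth - i))
    for i in range(path_index, unique_depth):
        fi[i] = fi[i + 1]
        zf[i] = zf[i + 1]
        of[i] = of[i + 1]


@njit(cache=False)
def _recurse(
    children_left,
    children_right,
    split_feature,
    threshold,
    values,
    node_weight,
    x,
    phi,
    node,
    unique_depth,
    pfi,
    pzf,
    pof,
    ppw,
    parent_zero_fraction,
    parent_one_fraction,
    parent_feature_index,
):
    # copy the parent path and extend it with the incoming split
    fi = np.empty(unique_depth + 1, np.int64)
    zf = np.empty(unique_depth + 1, np.float64)
    of = np.empty(unique_depth + 1, np.float64)
    pw = np.empty(unique_depth + 1, np.float64)
    for i in range(unique_depth):
        fi[i] = pfi[i]
        zf[i] = pzf[i]
        of[i] = pof[i]
        pw[i] = ppw[i]
    fi[unique_depth] = parent_feature_index
    zf[unique_depth] = parent_zero_fraction
    of[unique_depth] = parent_one_fraction
    pw[unique_depth] = 1.0 if unique_depth == 0 else 0.0
    for i in range(unique_depth - 1, -1, -1):
        pw[i + 1] += parent_one_fraction * pw[i] * (i + 1) / (unique_depth + 1.0)
        pw[i] = parent_zero_fraction * pw[i] * (unique_depth - i) / (unique_depth + 1.0)

    if children_left[node] < 0:  # leaf
        for i in range(1, unique_depth + 1):
            w = _unwound_path_sum(zf, of, pw, unique_depth, i)
            phi[fi[i]] += w * (of[i] - zf[i]) * values[node]
        return

    feat = split_feature[node]
    if x[feat] <= threshold[node]:
        hot, cold = children_left[node], children_right[node]
    else:
        hot, cold = children_right[node], children_left[node]
    w = node_weight[node]
    hot_zero_fraction = node_weight[hot] / w
    cold_zero_fraction = node_weight[cold] / w
    incoming_zero_fraction = 1.0
    incoming_one_fraction = 1.0

    # if this feature already appears on the path, undo its previous split
    path_index = 0
    while path_index <= unique_depth:
        if fi[path_index] == feat:
            break
        path_index += 1
    if path_index != unique_depth + 1:
        incoming_zero_fraction = zf[path_index]
        incoming_one_fraction = of[path_index]
        _unwind_path(fi, zf, of, pw, unique_depth, path_index)
        unique_depth -= 1

    _recurse(
        children_left,
        children_right,
        split_feature,
        threshold,
        values,
        node_weight,
        x,
        phi,
        hot,
        unique_depth + 1,
        fi,
        zf,
        of,
        pw,
        hot_zero_fraction * incoming_zero_fraction,
        incoming_one_fraction,
        feat,
    )
    _recurse(
        children_left,
        children_right,
        split_feature,
        threshold,
        values,
        node_weight,
        x,
        phi,
        cold,
        unique_depth + 1,
        fi,
        zf,
        of,
        pw,
        cold_zero_fraction * incoming_zero_fraction,
        0.0,
        feat,
    )


@njit(cache=False)
def _shap_one_tree(children_left, children_right, split_feature, threshold, values, node_weight, X, phi):
    n = X.shape[0]
    for s in range(n):
        fi0 = np.empty(1, np.int64)
        zf0 = np.empty(1, np.float64)
        of0 = np.empty(1, np.float64)
        pw0 = np.empty(1, np.float64)
        _recurse(
            children_left,
            children_right,
            split_feature,
            threshold,
            values,
            node_weight,
            X[s],
            phi[s],
            0,
            0,
            fi0,
            zf0,
            of0,
            pw0,
            1.0,
            1.0,
            -1,
        )


def tree_shap_values(
    children_left: np.ndarray,
    children_right: np.ndarray,
    split_feature: np.ndarray,
    threshold: np.ndarray,
    values: np.ndarray,
    node_weight: np.ndarray,
    X: np.ndarray,
) -> np.ndarray:
    """Shapley values of one tree for every row of ``X``.

    ``values`` holds the per-node scalar output (leaf prediction; internal
    nodes may carry the cover-weighted mean, only ``values[0]`` and leaf
    entries are read).  ``node_weight`` is the training cover per node and
    must be consistent (children sum to parent).  Returns an (n, m) array.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    _shap_one_tree(
        np.ascontiguousarray(children_left, dtype=np.int64),
        np.ascontiguousarray(children_right, dtype=np.int64),
        np.ascontiguousarray(split_feature, dtype=np.int64),
        np.ascontiguousarray(threshold, dtype=np.float64),
        np.ascontiguousarray(values, dtype=np.float64),
        np.ascontiguousarray(node_weight, dtype=np.float64),
        X,
        phi,
    )
    return phi


def expected_value(values: np.ndarray) -> float:
    """Cover-weighted mean prediction of a tree = its root node value."""
    return float(values[0])
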