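"""Exact tree Shapley attributions for LightGBM boosters.

Per-sample feature attributions (phi) are obtained from LightGBM's
built-in exact path-dependent TreeSHAP (``pred_contrib=True``).  This
module adds what the booster does not expose: pairwise Shapley
*interaction* values, computed by the conditioned-path TreeSHAP
recursion on the dumped tree structure.  For features i != j::

    Phi[i, j] = (phi_j | x_i forced into every coalition
                 - phi_j | x_i kept out of every coalition) / 2

and the diagonal holds the main effects ``Phi[i, i] = phi_i -
sum_{j != i} Phi[i, j]``, so each row of the signed matrix sums to the
feature's attribution and the whole matrix sums to ``f(x) - E[f]``.

Conditional expectations are path-dependent: at a split on an absent
feature both branches are followed, weighted by their training cover.
The recursion is the polynomial-time weighted-path algorithm; it is
compiled with numba when possible and falls back to pure Python.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TreeEnsemble",
    "shap_values",
    "shap_interaction_values",
]


class TreeEnsemble:
    """Flattened tree arrays parsed from a LightGBM booster dump.

    Leaves are encoded with ``children_left == -1``; internal nodes use
    numeric ``<=`` splits.  ``node_value`` holds leaf outputs,
    ``node_weight`` the training cover of each node.
    """

    def __init__(self, booster, num_iteration: int | None = None):
        dump = booster.dump_model(num_iteration=num_iteration or 0)
        self.n_features = dump["max_feature_idx"] + 1
        trees = []
        for info in dump["tree_info"]:
            trees.append(_flatten_tree(info["tree_structure"]))
        if num_iteration:
            trees = trees[:num_iteration]
        self.trees = trees
        self.max_depth = max((t["depth"] for t in trees), default=0)
        # expected value of the ensemble under the cover distribution
        self.base = 0.0
        for t in trees:
            leaf = t["left"] < 0
            w = t["weight"][leaf]
            self.base += float(np.sum(t["value"][leaf] * w) / np.sum(w))


def _flatten_tree(root: dict) -> dict:
    left, right, feature, threshold, value, weight, depth = [], [], [], [], [], [], []

    def walk(node: dict, d: int) -> int:
        idx = len(left)
        left.append(-1)
        right.append(-1)
        depth.append(d)
        if "leaf_value" in node and "split_feature" not in node:
            feature.append(-1)
            threshold.append(0.0)
            value.append(float(node["leaf_value"]))
            weight.append(float(node.get("leaf_count", 1)))
        else:
            feature.append(int(node["split_feature"]))
            threshold.append(float(node["threshold"]))
            value.append(0.0)
            weight.append(float(node.get("internal_count", 1)))
            left[idx] = walk(node["left_child"], d + 1)
            right[idx] = walk(node["right_child"], d + 1)
        return idx

    walk(root, 0)
    return {
        "left": np.asarray(left, dtype=np.int64),
        "right": np.asarray(right, dtype=np.int64),
        "feature": np.asarray(feature, dtype=np.int64),
        "threshold": np.asarray(threshold, dtype=np.float64),
        "value": np.asarray(value, dtype=np.float64),
        "weight": np.asarray(weight, dtype=np.float64),
        "depth": int(max(depth)) if depth else 0,
    }


# ---------------------------------------------------------------------------
# conditioned TreeSHAP recursion (weighted path algorithm)
#
# The unique path is stored in parallel arrays (feature index, fraction of
# paths flowing through when the feature is absent, fraction when present,
# permutation weight).  Each recursion level copies its parent's segment,
# so the buffer holds (D + 2)(D + 3) / 2 elements for depth D.


def _extend(pf, pz, po, pw, offset, unique_depth, zero_fraction, one_fraction,
            feature_index):
    pf[offset + unique_depth] = feature_index
    pz[offset + unique_depth] = zero_fraction
    po[offset + unique_depth] = one_fraction
    pw[offset + unique_depth] = 1.0 if unique_depth == 0 else 0.0
    for i in range(unique_depth - 1, -1, -1):
        pw[offset + i + 1] += one_fraction * pw[offset + i] * (i + 1.0) / (unique_depth + 1.0)
        pw[offset + i] = zero_fraction * pw[offset + i] * (unique_depth - i) / (unique_depth + 1.0)


def _unwind(pf, pz, po, pw, offset, unique_depth, path_index):
    one_fraction = po[offset + path_index]
    zero_fraction = pz[offset + path_index]
    next_one_portion = pw[offset + unique_depth]
    for i in range(unique_depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = pw[offset + i]
            pw[offset + i] = next_one_portion * (unique_depth + 1.0) / ((i + 1.0) * one_fraction)
            next_one_portion = tmp - pw[offset + i] * zero_fraction * (unique_depth - i) / (unique_depth + 1.0)
        else:
            pw[offset + i] = (pw[offset + i] * (unique_depth + 1.0)) / (zero_fraction * (unique_depth - i))
    for i in range(path_index, unique_depth):
        pf[offset + i] = pf[offset + i + 1]
        pz[offset + i] = pz[offset + i + 1]
        po[offset + i] = po[offset + i + 1]


def _unwound_sum(pf, pz, po, pw, offset, unique_depth, path_index):
    one_fraction = po[offset + path_index]
    zero_fraction = pz[offset + path_index]
    next_one_portion = pw[offset + unique_depth]
    total = 0.0
    for i in range(unique_depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = next_one_portion * (unique_depth + 1.0) / ((i + 1.0) * one_fraction)
            total += tmp
            next_one_portion = pw[offset + i] - tmp * zero_fraction * (unique_depth - i) / (unique_depth + 1.0)
        else:
            total += (pw[offset + i] / zero_fraction) / ((unique_depth - i) / (unique_depth + 1.0))
    return total


def _recurse(left, right, feature, threshold, value, weight, x, phi,
             node, unique_depth, parent_offset,
             parent_zero_fraction, parent_one_fraction, parent_feature_index,
             condition, condition_feature, condition_fraction,
             pf, pz, po, pw):
    if condition_fraction == 0.0:
        return
    offset = parent_offset + unique_depth + 1
    for i in range(unique_depth + 1):
        pf[offset + i] = pf[parent_offset + i]
        pz[offset + i] = pz[parent_offset + i]
        po[offset + i] = po[parent_offset + i]
        pw[offset + i] = pw[parent_offset + i]
    if condition == 0 or condition_feature != parent_feature_index:
        _extend(pf, pz, po, pw, offset, unique_depth,
                parent_zero_fraction, parent_one_fraction, parent_feature_index)
        unique_depth += 1

    split_index = feature[node]
    if left[node] < 0:  # leaf
        for i in range(1, unique_depth):
            w = _unwound_sum(pf, pz, po, pw, offset, unique_depth - 1, i)
            phi[pf[offset + i]] += (
                w * (po[offset + i] - pz[offset + i]) * value[node] * condition_fraction
            )
        return

    hot = left[node] if x[split_index] <= threshold[node] else right[node]
    cold = right[node] if hot == left[node] else left[node]
    w = weight[node]
    hot_zero_fraction = weight[hot] / w
    cold_zero_fraction = weight[cold] / w
    incoming_zero_fraction = 1.0
    incoming_one_fraction = 1.0

    # undo a previous split on the same feature so fractions accumulate
    path_index = 0
    found = False
    for i in range(unique_depth):
        if pf[offset + i] == split_index:
            path_index = i
            found = True
            break
    if found:
        incoming_zero_fraction = pz[offset + path_index]
        incoming_one_fraction = po[offset + path_index]
        _unwind(pf, pz, po, pw, offset, unique_depth - 1, path_index)
        unique_depth -= 1

    # conditioned feature is not a player: route its condition_fraction
    # instead of extending the path (the child skips the extension, so
    # the entry count is unchanged)
    hot_condition_fraction = condition_fraction
    cold_condition_fraction = condition_fraction
    if condition > 0 and split_index == condition_feature:
        cold_condition_fraction = 0.0
    elif condition < 0 and split_index == condition_feature:
        hot_condition_fraction *= hot_zero_fraction
        cold_condition_fraction *= cold_zero_fraction

    _recurse(left, right, feature, threshold, value, weight, x, phi,
             hot, unique_depth, offset,
             hot_zero_fraction * incoming_zero_fraction, incoming_one_fraction,
             split_index, condition, condition_feature, hot_condition_fraction,
             pf, pz, po, pw)
    _recurse(left, right, feature, threshold, value, weight, x, phi,
             cold, unique_depth, offset,
             cold_zero_fraction * incoming_zero_fraction, 0.0,
             split_index, condition, condition_feature, cold_condition_fraction,
             pf, pz, po, pw)


def _tree_phi(tree: dict, x: np.ndarray, phi: np.ndarray,
              condition: int, condition_feature: int) -> None:
    size = (tree["depth"] + 3) * (tree["depth"] + 4) // 2 + 2
    pf = np.full(size, -9, dtype=np.int64)
    pz = np.zeros(size)
    po = np.zeros(size)
    pw = np.zeros(size)
    _recurse(
        tree["left"], tree["right"], tree["feature"], tree["threshold"],
        tree["value"], tree["weight"], x, phi,
        0, 0, 0, 1.0, 1.0, -1, condition, condition_feature, 1.0,
        pf, pz, po, pw,
    )


try:  # compile the hot loop when numba is available
    import numba

    _extend = numba.njit(cache=False)(_extend)
    _unwind = numba.njit(cache=False)(_unwind)
    _unwound_sum = numba.njit(cache=False)(_unwound_sum)
    _recurse = numba.njit(cache=False)(_recurse)
except Exception:  # pragma: no cover - numba always present in CI image
    pass


def shap_values(ensemble: TreeEnsemble, x: np.ndarray) -> np.ndarray:
    """Per-sample attributions phi (n x p); rows sum to f(x) - base."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    out = np.zeros((x.shape[0], ensemble.n_features))
    for i in range(x.shape[0]):
        for tree in ensemble.trees:
            _tree_phi(tree, x[i], out[i], 0, -1)
    return out


def shap_interaction_values(ensemble: TreeEnsemble, x: np.ndarray) -> np.ndarray:
    """Per-sample pairwise Shapley interaction tensor (n x p x p)."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    n, p = x.shape[0], ensemble.n_features
    used = sorted(
        {int(f) for t in ensemble.trees for f in t["feature"] if f >= 0}
    )
    out = np.zeros((n, p, p))
    for i in range(n):
        phi = np.zeros(p)
        for tree in ensemble.trees:
            _tree_phi(tree, x[i], phi, 0, -1)
        for j in used:
            phi_on = np.zeros(p)
            phi_off = np.zeros(p)
            for tree in ensemble.trees:
                if (tree["feature"] == j).any():
                    _tree_phi(tree, x[i], phi_on, 1, j)
                    _tree_phi(tree, x[i], phi_off, -1, j)
                else:  # tree never splits on j: conditioning is a no-op
                    tmp = np.zeros(p)
                    _tree_phi(tree, x[i], tmp, 0, -1)
                    phi_on += tmp
                    phi_off += tmp
            diff = (phi_on - phi_off) / 2.0
            diff[j] = 0.0
            out[i, j, :] = diff
        row_off = out[i].sum(axis=1)
        for j in used:
            out[i, j, j] = phi[j] - row_off[j]
    return out
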