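"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (subset enumeration, explicit
step-up formulas, hand product-limit computation) and shares no code
with the package internals it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np


def tree_expectation(tree: dict, x: np.ndarray, S: frozenset) -> float:
    """Path-dependent conditional expectation E[f(x_S)] for one tree.

    Splits on features in S follow x; splits on absent features average
    both children weighted by their training cover.
    """

    def rec(i: int) -> float:
        if tree["left"][i] < 0:
            return float(tree["value"][i])
        f = int(tree["feature"][i])
        if f in S:
            nxt = tree["left"][i] if x[f] <= tree["threshold"][i] else tree["right"][i]
            return rec(nxt)
        wl = tree["weight"][tree["left"][i]]
        wr = tree["weight"][tree["right"][i]]
        return (wl * rec(tree["left"][i]) + wr * rec(tree["right"][i])) / (wl + wr)

    return rec(0)


def ensemble_value(trees: list[dict], x: np.ndarray, S) -> float:
    return sum(tree_expectation(t, x, frozenset(S)) for t in trees)


def brute_shapley(trees: list[dict], x: np.ndarray, n_features: int) -> np.ndarray:
    """Shapley values by enumeration over all feature subsets."""
    p = n_features
    phi = np.zeros(p)
    players = list(range(p))
    for j in players:
        rest = [f for f in players if f != j]
        for r in range(len(rest) + 1):
            for S in combinations(rest, r):
                w = factorial(r) * factorial(p - r - 1) / factorial(p)
                phi[j] += w * (
                    ensemble_value(trees, x, set(S) | {j})
                    - ensemble_value(trees, x, set(S))
                )
    return phi


def brute_shapley_interactions(
    trees: list[dict], x: np.ndarray, n_features: int
) -> np.ndarray:
    """Shapley interaction index by enumeration; diagonal holds main effects."""
    p = n_features
    out = np.zeros((p, p))
    players = list(range(p))
    for i in players:
        for j in players:
            if i == j:
                continue
            rest = [f for f in players if f not in (i, j)]
            for r in range(len(rest) + 1):
                for S in combinations(rest, r):
                    w = factorial(r) * factorial(p - r - 2) / (2 * factorial(p - 1))
                    out[i, j] += w * (
                        ensemble_value(trees, x, set(S) | {i, j})
                        - ensemble_value(trees, x, set(S) | {i})
                        - ensemble_value(trees, x, set(S) | {j})
                        + ensemble_value(trees, x, set(S))
                    )
    phi = brute_shapley(trees, x, p)
    for i in players:
        out[i, i] = phi[i] - out[i].sum()
    return out


def brute_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up by the definition: q_(i) is the
    minimum over j >= i of m * p_(j) / j, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for rank_i in range(m):
        q_sorted[rank_i] = min(
            min(m * p[order[j]] / (j + 1) for j in range(rank_i, m)), 1.0
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hand_km_incidence(durations, events) -> list[tuple[float, float]]:
    """Product-limit cumulative incidence at each distinct event time."""
    records = sorted(zip(durations, events))
    surv = 1.0
    out = []
    times = sorted({t for t, e in records if e})
    for t in times:
        at_risk = sum(1 for d, _ in records if d >= t)
        d = sum(1 for dt, e in records if e and dt == t)
        surv *= 1.0 - d / at_risk
        out.append((t, 1.0 - surv))
    return out
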