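"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written in the most literal way possible (python loops,
direct set arithmetic, pair counting) so that agreement with the package's
vectorised implementations is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def jaccard_oracle(sets: list[set]) -> np.ndarray:
    """Pairwise Jaccard by direct set enumeration; empty/disjoint pairs -> 0."""
    n = len(sets)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                S[i, j] = 1.0
                continue
            union = sets[i] | sets[j]
            inter = sets[i] & sets[j]
            S[i, j] = len(inter) / len(union) if union and inter else 0.0
    return S


def auc_oracle(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC by counting all positive/negative score comparisons, ties 1/2."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pr_oracle(pos: np.ndarray, neg: np.ndarray):
    """(threshold, recall, precision) by explicit sweep over distinct scores."""
    thresholds = sorted(set(list(pos) + list(neg)), reverse=True)
    points = []
    for t in thresholds:
        tp = sum(1 for s in pos if s >= t)
        fp = sum(1 for s in neg if s >= t)
        points.append((t, tp / len(pos), tp / (tp + fp) if tp + fp else 1.0))
    return points


def density_oracle(X: np.ndarray, radius: float) -> np.ndarray:
    """# other points within *radius* (Euclidean), by explicit double loop."""
    n = len(X)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.sqrt(((X[i] - X[j]) ** 2).sum()) <= radius:
                out[i] += 1
    return out


# --------------------------------------------------------------------------
# reference CART-style tree for the degenerate BRF limit
# --------------------------------------------------------------------------

def _gini_of_split(x, y, thr):
    left = [yi for xi, yi in zip(x, y) if xi <= thr]
    right = [yi for xi, yi in zip(x, y) if xi > thr]
    n = len(y)

    def gini(labels):
        if not labels:
            return 0.0
        p = sum(labels) / len(labels)
        return 1.0 - p * p - (1.0 - p) * (1.0 - p)

    return (len(left) * gini(left) + len(right) * gini(right)) / n


def reference_tree(X, y, config, rng):
    """CART-style Gini tree with ⌈√D⌉ feature bagging, mirroring the BRF rng
    protocol (B1 coin, feature draw, B2 coin at every split attempt) so that
    with p1 = p2 = 0 and shared structural/estimation data the two trees must
    coincide. Returns nested tuples: ('leaf', fraction) or
    (feature, threshold, left, right)."""
    D = X.shape[1]
    tol = 1e-12

    def build(idx, depth):
        labels = [y[i] for i in idx]
        fraction = sum(labels) / len(labels)
        if (
            len(idx) < config.min_split
            or depth >= config.max_depth
            or min(labels) == max(labels)
        ):
            return ("leaf", fraction)
        # mirror the Bernoulli protocol: B1 coin, candidate draw, B2 coin
        k = 1 if rng.random() < config.p1 else min(D, int(np.ceil(np.sqrt(D))))
        candidates = rng.choice(D, size=k, replace=False)
        assert rng.random() >= config.p2  # degenerate limit: impurity branch
        best = None
        for f in sorted(int(c) for c in candidates):
            xs = sorted({X[i, f] for i in idx})
            for a, b in zip(xs[:-1], xs[1:]):
                thr = (a + b) / 2.0
                g = _gini_of_split([X[i, f] for i in idx], labels, thr)
                if best is None or g < best[0] - tol:
                    best = (g, f, thr)
        if best is None:
            return ("leaf", fraction)
        _, f, thr = best
        left = [i for i in idx if X[i, f] <= thr]
        right = [i for i in idx if X[i, f] > thr]
        return (f, thr, build(left, depth + 1), build(right, depth + 1))

    return build(list(range(len(y))), 0)


def tree_to_tuple(node):
    """Convert a package TreeNode to the reference nested-tuple form."""
    if node.is_leaf:
        return ("leaf", node.positive_fraction)
    return (
        int(node.feature_index),
        float(node.threshold),
        tree_to_tuple(node.left),
        tree_to_tuple(node.right),
    )


def trees_equal(ref, got, atol=1e-9) -> bool:
    if ref[0] == "leaf" or got[0] == "leaf":
        return (
            ref[0] == "leaf"
            and got[0] == "leaf"
            and abs(ref[1] - got[1]) <= atol
        )
    return (
        ref[0] == got[0]
        and abs(ref[1] - got[1]) <= atol
        and trees_equal(ref[2], got[2], atol)
        and trees_equal(ref[3], got[3], atol)
    )
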