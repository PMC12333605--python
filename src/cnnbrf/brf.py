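"""Bernoulli Random Forest (BRF) classifier, written from scratch.

BRF departs from a classical random forest in three ways, each aimed at
theoretical consistency while keeping empirical accuracy:

1. **Structural/estimation split.** Each tree's sample is partitioned into a
   *structural* part, which alone shapes the tree (split search, stopping),
   and an *estimation* part, which alone fills the leaves with class-1
   fractions. Perturbing estimation labels can change leaf values but never
   the tree's shape.

2. **Bernoulli trial B1 — candidate features.** At every node a coin with
   probability ``p1`` decides whether a *single* uniformly chosen feature is
   the candidate set (probability ``p1``) or ⌈√D⌉ distinct features are
   (probability ``1 − p1``).

3. **Bernoulli trial B2 — split point.** A second coin with probability
   ``p2`` decides whether the split point is drawn uniformly at random from
   the candidate feature's value range (probability ``p2``) or found by
   exhaustive Gini-impurity search over candidate features × midpoints of
   consecutive distinct values (probability ``1 − p2``).

With ``p1 = p2 = 0`` and a shared structural/estimation sample the forest
degenerates to a plain CART-style Gini forest with ⌈√D⌉ feature bagging —
the reference against which the implementation is tested.

Routing convention: a sample goes left iff ``x[feature] <= threshold``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "BRFConfig",
    "TreeNode",
    "BRFModel",
    "split_structural_estimation",
    "select_candidate_features",
    "choose_split",
    "grow_tree",
    "fit",
    "predict_proba",
]

_GINI_TIE_TOL = 1e-12


@dataclass(frozen=True)
class BRFConfig:
    """Forest hyperparameters.

    ``p1``/``p2`` are the Bernoulli probabilities of the single-feature and
    random-split branches; both default to 0.05 so trees stay close to
    deterministic Gini trees while the Bernoulli mechanism remains active.
    ``share_data=True`` is the degenerate test mode in which the whole
    per-tree sample serves as both structural and estimation part.
    """

    n_trees: int = 100
    p1: float = 0.05
    p2: float = 0.05
    min_split: int = 10
    max_depth: int = 25
    bootstrap: bool = True
    structural_fraction: float = 0.5
    seed: int = 0
    share_data: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p1 <= 1.0 and 0.0 <= self.p2 <= 1.0):
            raise ConfigurationError("p1 and p2 must lie in [0, 1]")
        if not 0.0 < self.structural_fraction < 1.0:
            raise ConfigurationError("structural_fraction must lie in (0, 1)")
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.min_split < 2:
            raise ConfigurationError("min_split must be >= 2")
        if self.max_depth < 0:
            raise ConfigurationError("max_depth must be >= 0")


class TreeNode:
    """Binary tree node; a leaf carries the estimation-sample class fraction."""

    __slots__ = ("feature_index", "threshold", "left", "right",
                 "positive_fraction", "estimation_count")

    def __init__(
        self,
        *,
        feature_index: int | None = None,
        threshold: float | None = None,
        left: "TreeNode | None" = None,
        right: "TreeNode | None" = None,
        positive_fraction: float = 0.0,
        estimation_count: int = 0,
    ) -> None:
        self.feature_index = feature_index
        self.threshold = threshold
        self.left = left
        self.right = right
        self.positive_fraction = positive_fraction
        self.estimation_count = estimation_count

    @property
    def is_leaf(self) -> bool:
        return self.feature_index is None

    def structure(self) -> tuple:
        """Shape signature: split features/thresholds only, no leaf values."""
        if self.is_leaf:
            return ("leaf",)
        return (
            int(self.feature_index),
            round(float(self.threshold), 12),
            self.left.structure(),
            self.right.structure(),
        )

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {
                "leaf": True,
                "positive_fraction": self.positive_fraction,
                "estimation_count": self.estimation_count,
            }
        return {
            "leaf": False,
            "feature_index": self.feature_index,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if d["leaf"]:
            return cls(
                positive_fraction=d["positive_fraction"],
                estimation_count=d["estimation_count"],
            )
        return cls(
            feature_index=d["feature_index"],
            threshold=d["threshold"],
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


def split_structural_estimation(
    sample_indices: np.ndarray,
    structural_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint partition; |structural| = round-half-up(fraction·n)."""
    idx = np.asarray(sample_indices)
    n = len(idx)
    if n < 2:
        raise ConfigurationError("need at least 2 samples to partition")
    n_struct = int(np.floor(n * structural_fraction + 0.5))
    n_struct = min(max(n_struct, 1), n - 1)
    perm = rng.permutation(idx)
    return perm[:n_struct], perm[n_struct:]


def select_candidate_features(
    D: int, p1: float, rng: np.random.Generator
) -> np.ndarray:
    """B1: one uniform feature with probability p1, else ⌈√D⌉ distinct ones."""
    if D < 1:
        raise ConfigurationError("need at least one feature")
    k = 1 if rng.random() < p1 else min(D, int(np.ceil(np.sqrt(D))))
    return rng.choice(D, size=k, replace=False)


def _gini_best_for_feature(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Best (gini, threshold) over midpoints of consecutive distinct values."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    boundary = np.flatnonzero(xs[:-1] < xs[1:])
    if boundary.size == 0:
        return None
    n = len(xs)
    cum_pos = np.cumsum(ys)
    total_pos = cum_pos[-1]
    nl = boundary + 1.0
    nr = n - nl
    pos_l = cum_pos[boundary]
    pos_r = total_pos - pos_l
    gini_l = 1.0 - (pos_l / nl) ** 2 - (1.0 - pos_l / nl) ** 2
    gini_r = 1.0 - (pos_r / nr) ** 2 - (1.0 - pos_r / nr) ** 2
    g = (nl * gini_l + nr * gini_r) / n
    thr = (xs[boundary] + xs[boundary + 1]) / 2.0
    # smallest threshold among tied minima
    best = np.flatnonzero(g <= g.min() + _GINI_TIE_TOL)[0]
    return float(g[best]), float(thr[best])


def choose_split(
    X: np.ndarray,
    y: np.ndarray,
    candidates: np.ndarray,
    p2: float,
    rng: np.random.Generator,
) -> tuple[int, float] | None:
    """B2: random split point with probability p2, Gini-optimal otherwise.

    Returns ``(feature_index, threshold)`` or None when every candidate
    feature is constant within the node. Gini ties break toward the lowest
    feature index, then the smallest threshold.
    """
    candidates = np.sort(np.asarray(candidates))
    if rng.random() < p2:
        spans = [
            (f, X[:, f].min(), X[:, f].max())
            for f in candidates
            if X[:, f].min() < X[:, f].max()
        ]
        if not spans:
            return None
        f, lo, hi = spans[rng.integers(len(spans))]
        return int(f), float(rng.uniform(lo, hi))
    best: tuple[float, int, float] | None = None
    for f in candidates:
        res = _gini_best_for_feature(X[:, f], y)
        if res is None:
            continue
        g, thr = res
        if best is None or g < best[0] - _GINI_TIE_TOL:
            best = (g, int(f), thr)
    if best is None:
        return None
    return best[1], best[2]


def grow_tree(
    Xs: np.ndarray,
    ys: np.ndarray,
    Xe: np.ndarray,
    ye: np.ndarray,
    config: BRFConfig,
    rng: np.random.Generator,
) -> TreeNode:
    """Grow one Bernoulli tree.

    Structural samples (``Xs, ys``) drive every split and stopping decision;
    estimation samples (``Xe, ye``) are only routed down and aggregated into
    leaf class fractions. Leaves reached by no estimation sample inherit the
    fraction of the nearest ancestor that saw at least one (the root
    fallback is the global estimation fraction).
    """
    if len(Xs) == 0:
        raise ConfigurationError("structural set is empty")
    D = Xs.shape[1]
    global_fraction = float(ye.mean()) if len(ye) else 0.5

    def build(s_idx: np.ndarray, e_idx: np.ndarray, depth: int, inherited: float) -> TreeNode:
        e_count = len(e_idx)
        fraction = float(ye[e_idx].mean()) if e_count else inherited
        labels = ys[s_idx]
        if (
            len(s_idx) < config.min_split
            or depth >= config.max_depth
            or labels.min() == labels.max()
        ):
            return TreeNode(positive_fraction=fraction, estimation_count=e_count)
        candidates = select_candidate_features(D, config.p1, rng)
        split = choose_split(Xs[s_idx], labels, candidates, config.p2, rng)
        if split is None:
            return TreeNode(positive_fraction=fraction, estimation_count=e_count)
        f, thr = split
        s_left = s_idx[Xs[s_idx, f] <= thr]
        s_right = s_idx[Xs[s_idx, f] > thr]
        if len(s_left) == 0 or len(s_right) == 0:
            # a random threshold can fall outside the occupied range
            return TreeNode(positive_fraction=fraction, estimation_count=e_count)
        e_left = e_idx[Xe[e_idx, f] <= thr]
        e_right = e_idx[Xe[e_idx, f] > thr]
        return TreeNode(
            feature_index=f,
            threshold=thr,
            left=build(s_left, e_left, depth + 1, fraction),
            right=build(s_right, e_right, depth + 1, fraction),
            positive_fraction=fraction,
            estimation_count=e_count,
        )

    return build(
        np.arange(len(Xs)), np.arange(len(Xe)), 0, global_fraction
    )


@dataclass
class BRFModel:
    """A fitted forest: tree roots plus the config that produced them."""

    trees: list[TreeNode]
    config: BRFConfig
    n_features: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_proba(self, X)

    def structure_hashes(self) -> list[int]:
        return [hash(t.structure()) for t in self.trees]

    # -- text serialisation (diffable JSON) -------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "config": asdict(self.config),
                "n_features": self.n_features,
                "trees": [t.to_dict() for t in self.trees],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BRFModel":
        d = json.loads(text)
        return cls(
            trees=[TreeNode.from_dict(t) for t in d["trees"]],
            config=BRFConfig(**d["config"]),
            n_features=d["n_features"],
        )


def fit(X: np.ndarray, y: np.ndarray, config: BRFConfig | None = None) -> BRFModel:
    """Fit a Bernoulli random forest.

    Each tree draws its own rng stream (seed + tree index), its own
    bootstrap sample (when enabled) and its own structural/estimation
    partition, so refitting with the same seed reproduces the forest
    exactly.
    """
    config = config or BRFConfig()
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y).astype(np.int8).ravel()
    if X.ndim != 2 or len(X) != len(y):
        raise ConfigurationError("X must be 2-D with one label per row")
    if len(y) < 2:
        raise ConfigurationError("need at least 2 training samples")
    if y.min() == y.max():
        raise ConfigurationError("training labels contain a single class")
    n = len(y)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_trees)
    trees = []
    for t in range(config.n_trees):
        rng = np.random.default_rng(streams[t])
        sample = rng.integers(0, n, n) if config.bootstrap else np.arange(n)
        if config.share_data:
            s_idx = e_idx = sample
        else:
            s_idx, e_idx = split_structural_estimation(
                sample, config.structural_fraction, rng
            )
        trees.append(grow_tree(X[s_idx], y[s_idx], X[e_idx], y[e_idx], config, rng))
    return BRFModel(trees=trees, config=config, n_features=X.shape[1])


def _route(node: TreeNode, X: np.ndarray, idx: np.ndarray, out: np.ndarray) -> None:
    if node.is_leaf:
        out[idx] = node.positive_fraction
        return
    go_left = X[idx, node.feature_index] <= node.threshold
    _route(node.left, X, idx[go_left], out)
    _route(node.right, X, idx[~go_left], out)


def predict_proba(model: BRFModel, X: np.ndarray) -> np.ndarray:
    """Mean over trees of the leaf positive fraction each row routes to."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ConfigurationError(
            f"expected {model.n_features} features, got shape {X.shape}"
        )
    scores = np.zeros(X.shape[0])
    leaf = np.empty(X.shape[0])
    idx = np.arange(X.shape[0])
    for tree in model.trees:
        _route(tree, X, idx, leaf)
        scores += leaf
    return scores / len(model.trees)
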