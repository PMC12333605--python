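"""Pair feature vectors and balanced training-set assembly.

Every microbe-drug pair (d_u, m_v) is represented by the concatenation
[row v of SM, row u of SD]: the microbe block (length nm) first, then the
drug block (length nd), giving nm + nd features. Labels come only from the
adjacency matrix; the features themselves never see A.

Negative samples are drawn from the unlabeled pairs either uniformly at
random or by density-aware stratified sampling (DAS): pairs are sorted by
local feature-space density and picked at fixed intervals so every density
stratum is represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .data_io import AssociationDataset
from .exceptions import ConfigurationError, SamplingError
from .similarity import IntegratedSimilarities

__all__ = [
    "PairSample",
    "PairSet",
    "TrainingSet",
    "pair_vector",
    "feature_matrix",
    "enumerate_pairs",
    "sample_negatives_random",
    "sample_negatives_das",
    "build_training_set",
]

#: feature layout tag recorded alongside trained models
FEATURE_LAYOUT = "microbe_block_then_drug_block"

UNLABELED = -1

#: default cap on the number of pool points used for exact density computation
DAS_DENSITY_CAP = 20_000


@dataclass(frozen=True)
class PairSample:
    """One microbe-drug pair: indices, feature vector and label (1/0/None)."""

    drug_index: int
    microbe_index: int
    features: np.ndarray
    label: int | None


@dataclass(frozen=True)
class PairSet:
    """Vectorised collection of pairs; label −1 marks unlabeled pairs."""

    drug_index: np.ndarray
    microbe_index: np.ndarray
    label: np.ndarray  # int8: 1, 0, or −1 (unlabeled)

    def __post_init__(self) -> None:
        for name in ("drug_index", "microbe_index", "label"):
            object.__setattr__(
                self, name, np.ascontiguousarray(getattr(self, name)).ravel()
            )
        if not (len(self.drug_index) == len(self.microbe_index) == len(self.label)):
            raise ConfigurationError("pair arrays must have equal length")

    def __len__(self) -> int:
        return len(self.drug_index)

    def subset(self, idx: np.ndarray) -> "PairSet":
        return PairSet(self.drug_index[idx], self.microbe_index[idx], self.label[idx])

    def with_label(self, value: int) -> "PairSet":
        return PairSet(
            self.drug_index,
            self.microbe_index,
            np.full(len(self), value, dtype=np.int8),
        )

    def keys(self) -> set[tuple[int, int]]:
        return set(zip(self.drug_index.tolist(), self.microbe_index.tolist()))


@dataclass(frozen=True)
class TrainingSet:
    """Balanced positives/negatives for encoder and forest training."""

    positives: PairSet
    negatives: PairSet
    seed: int

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ConfigurationError(
                f"unbalanced training set: {len(self.positives)} positives vs "
                f"{len(self.negatives)} negatives"
            )
        if self.positives.keys() & self.negatives.keys():
            raise ConfigurationError("a pair appears as both positive and negative")

    @property
    def pairs(self) -> PairSet:
        return PairSet(
            np.concatenate([self.positives.drug_index, self.negatives.drug_index]),
            np.concatenate([self.positives.microbe_index, self.negatives.microbe_index]),
            np.concatenate(
                [
                    np.ones(len(self.positives), dtype=np.int8),
                    np.zeros(len(self.negatives), dtype=np.int8),
                ]
            ),
        )

    def design(self, sims: IntegratedSimilarities) -> tuple[np.ndarray, np.ndarray]:
        """Feature matrix and 0/1 label vector, positives first."""
        pairs = self.pairs
        return feature_matrix(pairs, sims), pairs.label.astype(np.float64)


def pair_vector(u: int, v: int, sims: IntegratedSimilarities) -> np.ndarray:
    """Feature vector for pair (drug u, microbe v): [SM row v, SD row u]."""
    if not 0 <= u < sims.n_drugs:
        raise IndexError(f"drug index {u} out of range [0, {sims.n_drugs})")
    if not 0 <= v < sims.n_microbes:
        raise IndexError(f"microbe index {v} out of range [0, {sims.n_microbes})")
    return np.concatenate([sims.SM[v], sims.SD[u]])


def feature_matrix(pairs: PairSet, sims: IntegratedSimilarities) -> np.ndarray:
    """Row-per-pair feature matrix, shape (len(pairs), nm + nd)."""
    return np.hstack([sims.SM[pairs.microbe_index], sims.SD[pairs.drug_index]])


def enumerate_pairs(dataset: AssociationDataset) -> PairSet:
    """All nd × nm pairs in drug-major order; A==1 → label 1, else unlabeled."""
    nd, nm = dataset.n_drugs, dataset.n_microbes
    du, mv = np.meshgrid(np.arange(nd), np.arange(nm), indexing="ij")
    label = np.where(dataset.A.ravel() == 1, 1, UNLABELED).astype(np.int8)
    return PairSet(du.ravel(), mv.ravel(), label)


def _check_pool(pool: PairSet, n: int) -> None:
    if n < 0:
        raise ConfigurationError("sample count must be non-negative")
    if len(pool) < n:
        raise SamplingError(f"pool of {len(pool)} pairs cannot supply {n} negatives")


def sample_negatives_random(pool: PairSet, n: int, seed: int) -> PairSet:
    """Uniform sample of *n* distinct pool pairs, labelled 0."""
    _check_pool(pool, n)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return pool.subset(idx).with_label(0)


def pair_densities(
    X: np.ndarray,
    radius: float | None,
    *,
    cap: int = DAS_DENSITY_CAP,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Neighbourhood density of each row of X: # other points within *radius*.

    ``radius=None`` selects the automatic radius — the 25th percentile of
    pairwise Euclidean distances in a seeded subsample of up to 1000 points.
    Pools larger than *cap* are handled by counting neighbours against a
    seeded subsample of that size (scaled back to full-pool counts).
    """
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    if radius is None:
        m = min(1000, n)
        sub = X[rng.choice(n, size=m, replace=False)] if m < n else X
        d = cdist(sub, sub)
        radius = float(np.percentile(d[np.triu_indices(m, k=1)], 25)) if m > 1 else 1.0
    if radius <= 0:
        raise ConfigurationError(f"DAS radius must be positive, got {radius}")

    if n <= cap:
        ref, scale = X, 1.0
        exact = True
    else:
        ref = X[rng.choice(n, size=cap, replace=False)]
        scale = n / cap
        exact = False
    counts = np.empty(n, dtype=np.float64)
    block = max(1, int(2e7 // max(ref.shape[0], 1)))
    for start in range(0, n, block):
        stop = min(start + block, n)
        d = cdist(X[start:stop], ref)
        within = (d <= radius).sum(axis=1)
        counts[start:stop] = within
    if exact:
        counts -= 1  # each point is its own neighbour at distance 0
    else:
        counts = counts * scale - 1
    return np.maximum(counts, 0), radius


def sample_negatives_das(
    pool: PairSet,
    n: int,
    sims: IntegratedSimilarities,
    *,
    radius: float | None = None,
    seed: int = 0,
    density_cap: int = DAS_DENSITY_CAP,
) -> PairSet:
    """Density-aware stratified negative sampling.

    Densities are computed on raw pair feature vectors, the pool is sorted
    by density (descending, ties broken by pool position) and every
    ⌊k·|pool|/n⌋-th entry of the sorted list is selected — systematic
    sampling across the whole density spectrum.
    """
    _check_pool(pool, n)
    if n == 0:
        return pool.subset(np.array([], dtype=int)).with_label(0)
    X = feature_matrix(pool, sims)
    density, _ = pair_densities(X, radius, cap=density_cap, seed=seed)
    # descending density, stable tie-break on pool index
    order = np.lexsort((np.arange(len(pool)), -density))
    picks = order[(np.arange(n) * len(pool)) // n]
    return pool.subset(picks).with_label(0)


def build_training_set(
    dataset: AssociationDataset,
    sims: IntegratedSimilarities,
    *,
    sampler: str = "random",
    seed: int = 0,
    radius: float | None = None,
) -> TrainingSet:
    """Positives = all A==1 pairs; negatives sampled 1:1 from the unlabeled pool."""
    pairs = enumerate_pairs(dataset)
    pos = pairs.subset(np.flatnonzero(pairs.label == 1))
    pool = pairs.subset(np.flatnonzero(pairs.label == UNLABELED))
    n = len(pos)
    if sampler == "random":
        neg = sample_negatives_random(pool, n, seed)
    elif sampler == "das":
        neg = sample_negatives_das(pool, n, sims, radius=radius, seed=seed)
    else:
        raise ConfigurationError(f"unknown sampler {sampler!r} (random|das)")
    return TrainingSet(pos.with_label(1), neg, seed)
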