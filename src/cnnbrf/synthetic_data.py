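"""Seeded synthetic data with planted block structure.

The generator emulates the statistical premise of similarity-based
association prediction: drugs and microbes fall into co-association
blocks, entities in the same block are similar (≈0.8) and share
associations (high within-block density), entities in different blocks
are weakly similar (≈0.1) and rarely associated. Side-effect profiles are
drawn so that Jaccard similarity tracks block membership. Everything is
reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import (
    AssociationDataset,
    EntityCatalog,
    RawSimilarityMatrix,
    SideEffectProfiles,
)
from .exceptions import ConfigurationError

__all__ = ["SyntheticSpec", "generate", "generate_worked_micro", "shuffle_associations"]

SIM_WITHIN_BLOCK = 0.8
SIM_CROSS_BLOCK = 0.1


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-block generator.

    The defaults (120 drugs × 40 microbes in 4 blocks, within/background
    association densities 0.3/0.01, similarity noise 0.05) give a dataset
    whose similarity blocks genuinely predict associations, so the full
    pipeline should separate held-out positives from the unlabeled pool.
    """

    nd: int = 120
    nm: int = 40
    n_blocks: int = 4
    assoc_density_in: float = 0.3
    assoc_density_out: float = 0.01
    sim_noise: float = 0.05
    n_side_effect_terms: int = 60
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0.0 <= self.assoc_density_out < self.assoc_density_in <= 1.0:
            raise ConfigurationError(
                "need 0 <= assoc_density_out < assoc_density_in <= 1"
            )
        if not (self.nd >= self.n_blocks >= 1 and self.nm >= self.n_blocks):
            raise ConfigurationError("need nd, nm >= n_blocks >= 1")
        if self.sim_noise < 0:
            raise ConfigurationError("sim_noise must be >= 0")
        if self.n_side_effect_terms < self.n_blocks:
            raise ConfigurationError("need at least one side-effect term per block")


def _blocks(n: int, n_blocks: int) -> np.ndarray:
    """Contiguous near-equal partition: entity i -> block i*n_blocks//n."""
    return (np.arange(n) * n_blocks) // n


def _block_similarity(
    labels: np.ndarray, noise: float, rng: np.random.Generator
) -> np.ndarray:
    same = labels[:, None] == labels[None, :]
    S = np.where(same, SIM_WITHIN_BLOCK, SIM_CROSS_BLOCK)
    if noise > 0:
        E = rng.uniform(-noise, noise, S.shape)
        S = S + (E + E.T) / 2.0
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate(
    spec: SyntheticSpec | None = None,
) -> tuple[AssociationDataset, RawSimilarityMatrix, SideEffectProfiles, RawSimilarityMatrix]:
    """Draw (associations, drug-structure similarity, side effects, microbe similarity)."""
    spec = spec or SyntheticSpec()
    ss = np.random.SeedSequence(spec.seed)
    rng_A, rng_ds, rng_ms, rng_se = (np.random.default_rng(c) for c in ss.spawn(4))

    drugs = EntityCatalog.from_iterable(f"drug_{i:04d}" for i in range(spec.nd))
    microbes = EntityCatalog.from_iterable(f"microbe_{j:03d}" for j in range(spec.nm))
    db = _blocks(spec.nd, spec.n_blocks)
    mb = _blocks(spec.nm, spec.n_blocks)

    same_block = db[:, None] == mb[None, :]
    p = np.where(same_block, spec.assoc_density_in, spec.assoc_density_out)
    A = (rng_A.random((spec.nd, spec.nm)) < p).astype(np.int8)
    dataset = AssociationDataset(drugs, microbes, A)

    drug_sim = RawSimilarityMatrix(drugs, _block_similarity(db, spec.sim_noise, rng_ds))
    microbe_sim = RawSimilarityMatrix(
        microbes, _block_similarity(mb, spec.sim_noise, rng_ms)
    )

    # side-effect vocabulary: one core term group per block + a shared noise pool
    terms = [f"se_{t:03d}" for t in range(spec.n_side_effect_terms)]
    core_size = max(1, spec.n_side_effect_terms // (2 * spec.n_blocks))
    cores = [
        terms[b * core_size : (b + 1) * core_size] for b in range(spec.n_blocks)
    ]
    pool = terms[spec.n_blocks * core_size :]
    profiles = {}
    for i, d in enumerate(drugs):
        mine = {t for t in cores[db[i]] if rng_se.random() < 0.9}
        mine |= {t for t in pool if rng_se.random() < 0.05}
        if mine:
            profiles[d] = frozenset(mine)
    return dataset, drug_sim, SideEffectProfiles(profiles), microbe_sim


def generate_worked_micro() -> tuple[
    AssociationDataset, RawSimilarityMatrix, SideEffectProfiles, RawSimilarityMatrix
]:
    """Fixed 4-drug × 3-microbe miniature with hand-written matrices.

    Side-effect sets are d1:{a,b}, d2:{b,c}, d3:{a,b,c}, d4:∅, so the
    Jaccard matrix has SS1(d1,d2)=1/3, SS1(d1,d3)=SS1(d2,d3)=2/3 and zero
    for every pair involving d4. The structure matrix contains entries on
    both sides of the 0.5 cutoff. All intermediates are asserted
    step-by-step in the test suite.
    """
    drugs = EntityCatalog(("d1", "d2", "d3", "d4"))
    microbes = EntityCatalog(("m1", "m2", "m3"))
    A = np.array(
        [[1, 0, 0],
         [1, 1, 0],
         [0, 0, 1],
         [0, 1, 0]], dtype=np.int8
    )
    ss2 = np.array(
        [[1.0, 0.6, 0.2, 0.0],
         [0.6, 1.0, 0.5, 0.1],
         [0.2, 0.5, 1.0, 0.0],
         [0.0, 0.1, 0.0, 1.0]]
    )
    mv = np.array(
        [[1.0, 0.7, 0.2],
         [0.7, 1.0, 0.3],
         [0.2, 0.3, 1.0]]
    )
    profiles = SideEffectProfiles(
        {
            "d1": frozenset({"a", "b"}),
            "d2": frozenset({"b", "c"}),
            "d3": frozenset({"a", "b", "c"}),
        }
    )
    return (
        AssociationDataset(drugs, microbes, A),
        RawSimilarityMatrix(drugs, ss2),
        profiles,
        RawSimilarityMatrix(microbes, mv),
    )


def shuffle_associations(dataset: AssociationDataset, seed: int) -> AssociationDataset:
    """Null model: same number of associations placed uniformly at random.

    Destroys any relation between similarity blocks and the adjacency
    matrix, so a sound pipeline should score near AUC 0.5.
    """
    rng = np.random.default_rng(seed)
    n_ones = dataset.n_associations
    flat = np.zeros(dataset.n_drugs * dataset.n_microbes, dtype=np.int8)
    flat[rng.choice(flat.size, size=n_ones, replace=False)] = 1
    return AssociationDataset(
        dataset.drugs, dataset.microbes, flat.reshape(dataset.A.shape)
    )
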