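"""Integrated drug and microbe similarity.

Drug similarity fuses two views: Jaccard similarity of side-effect term
sets, and a chemical-structure similarity matrix (SIMCOMP-style scores)
with a hard cutoff below which entries are zeroed. The integrated drug
similarity is their elementwise average. Microbe similarity is the
sequence-identity matrix used as-is — no Gaussian-kernel augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import (
    EntityCatalog,
    RawSimilarityMatrix,
    SideEffectProfiles,
    check_alignment,
)
from .exceptions import ConfigurationError

__all__ = [
    "IntegratedSimilarities",
    "jaccard_similarity",
    "apply_structure_cutoff",
    "integrate",
]

DEFAULT_STRUCTURE_CUTOFF = 0.5


@dataclass(frozen=True)
class IntegratedSimilarities:
    """Integrated drug (``SD``) and microbe (``SM``) similarity matrices."""

    drugs: EntityCatalog
    microbes: EntityCatalog
    SD: np.ndarray
    SM: np.ndarray

    def __post_init__(self) -> None:
        for name, S, cat in (("SD", self.SD, self.drugs), ("SM", self.SM, self.microbes)):
            S = np.ascontiguousarray(S, dtype=np.float64)
            n = len(cat)
            if S.shape != (n, n):
                raise ConfigurationError(f"{name} shape {S.shape} != ({n}, {n})")
            object.__setattr__(self, name, S)

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_microbes(self) -> int:
        return len(self.microbes)


def jaccard_similarity(
    profiles: SideEffectProfiles, drugs: EntityCatalog
) -> RawSimilarityMatrix:
    """Side-effect similarity: |N(i) ∩ N(j)| / |N(i) ∪ N(j)|.

    Pairs with no common side effects (including pairs where either set is
    empty) score 0; the diagonal is 1 by convention.
    """
    n = len(drugs)
    sets = [profiles.get(d) for d in drugs]
    S = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        Ni = sets[i]
        if not Ni:
            continue
        for j in range(i + 1, n):
            Nj = sets[j]
            if not Nj:
                continue
            inter = len(Ni & Nj)
            if inter:
                S[i, j] = S[j, i] = inter / len(Ni | Nj)
    np.fill_diagonal(S, 1.0)
    return RawSimilarityMatrix(drugs, S)


def apply_structure_cutoff(
    ss2_raw: RawSimilarityMatrix,
    cutoff: float = DEFAULT_STRUCTURE_CUTOFF,
    *,
    binarize: bool = False,
) -> RawSimilarityMatrix:
    """Zero off-diagonal structure similarities strictly below *cutoff*.

    Entries at or above the cutoff are kept at their continuous value
    (``binarize=True`` sets them to 1 instead); the diagonal is untouched.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ConfigurationError(f"cutoff must lie in [0, 1], got {cutoff}")
    S = ss2_raw.S.copy()
    off = ~np.eye(S.shape[0], dtype=bool)
    below = off & (S < cutoff)
    S[below] = 0.0
    if binarize:
        S[off & (S >= cutoff)] = 1.0
    return RawSimilarityMatrix(ss2_raw.entities, S)


def integrate(
    ss1: RawSimilarityMatrix,
    ss2: RawSimilarityMatrix,
    mv: RawSimilarityMatrix,
    *,
    renormalize: bool = False,
) -> IntegratedSimilarities:
    """Fuse the similarity views into the integrated matrices.

    ``SD = (SS1 + SS2) / 2`` elementwise; ``SM`` is the microbe sequence
    similarity passed through unchanged. With ``renormalize=True`` each SD
    entry is instead averaged over the sources that are non-zero for that
    pair (for drugs with no side-effect records), rather than the literal
    two-source mean.
    """
    check_alignment(ss1.entities, ss2.entities, "side-effect vs structure similarity")
    if renormalize:
        n_sources = (ss1.S > 0).astype(np.float64) + (ss2.S > 0).astype(np.float64)
        with np.errstate(invalid="ignore"):
            SD = np.where(n_sources > 0, (ss1.S + ss2.S) / np.maximum(n_sources, 1), 0.0)
    else:
        SD = (ss1.S + ss2.S) / 2.0
    np.fill_diagonal(SD, 1.0)
    return IntegratedSimilarities(ss1.entities, mv.entities, SD, mv.S.copy())
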