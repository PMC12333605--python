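"""Containers and readers for association tables, similarity matrices and
side-effect profiles.

The on-disk formats are deliberately plain:

* association table — delimited text with a header naming the drug and
  microbe columns, one known association per row;
* similarity matrix — CSV with an identifier header row and identifier
  first column;
* side effects — two-column delimited text ``drug<TAB>side_effect``.

Entity catalogs preserve order of first appearance, and that order fixes
row/column order in every downstream matrix.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    ConfigurationError,
    DataFormatError,
    EmptyDatasetError,
    RangeError,
    SymmetryError,
)

__all__ = [
    "EntityCatalog",
    "AssociationDataset",
    "SideEffectProfiles",
    "RawSimilarityMatrix",
    "load_association_table",
    "load_similarity_matrix",
    "load_side_effects",
    "save_dataset",
    "save_matrix",
    "save_side_effects",
]

_SYMMETRY_TOL = 1e-6
_VALUE_TOL = 1e-9


@dataclass(frozen=True)
class EntityCatalog:
    """Ordered, duplicate-free list of entity identifiers (drugs or microbes).

    The catalog fixes the 0-based position of every entity; all matrices in
    the package are indexed by these positions.
    """

    ids: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index = {e: i for i, e in enumerate(self.ids)}
        if len(index) != len(self.ids):
            raise DataFormatError("entity identifiers must be unique")
        object.__setattr__(self, "_index", index)

    @classmethod
    def from_iterable(cls, ids: Iterable[str]) -> "EntityCatalog":
        """Build a catalog keeping the order of first appearance."""
        seen: dict[str, None] = {}
        for e in ids:
            e = str(e).strip()
            if e and e not in seen:
                seen[e] = None
        return cls(tuple(seen))

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, entity: str) -> bool:
        return entity in self._index

    def __iter__(self):
        return iter(self.ids)

    def position(self, entity: str) -> int:
        """0-based position of *entity*; KeyError when absent."""
        return self._index[entity]


@dataclass(frozen=True)
class AssociationDataset:
    """Known microbe-drug associations as a binary adjacency matrix.

    ``A`` has one row per drug and one column per microbe; ``A[i, j] == 1``
    iff drug ``i`` is known to associate with microbe ``j``.
    """

    drugs: EntityCatalog
    microbes: EntityCatalog
    A: np.ndarray

    def __post_init__(self) -> None:
        A = np.ascontiguousarray(self.A, dtype=np.int8)
        if A.shape != (len(self.drugs), len(self.microbes)):
            raise DataFormatError(
                f"adjacency shape {A.shape} does not match catalogs "
                f"({len(self.drugs)}, {len(self.microbes)})"
            )
        if not np.isin(A, (0, 1)).all():
            raise DataFormatError("adjacency entries must be 0 or 1")
        object.__setattr__(self, "A", A)

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_microbes(self) -> int:
        return len(self.microbes)

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    def copy(self) -> "AssociationDataset":
        return AssociationDataset(self.drugs, self.microbes, self.A.copy())


@dataclass(frozen=True)
class SideEffectProfiles:
    """Drug identifier -> set of side-effect terms; absent drugs map to ∅."""

    profiles: Mapping[str, frozenset[str]]

    def get(self, drug: str) -> frozenset[str]:
        return self.profiles.get(drug, frozenset())

    def __len__(self) -> int:
        return len(self.profiles)


@dataclass(frozen=True)
class RawSimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] with unit diagonal."""

    entities: EntityCatalog
    S: np.ndarray

    def __post_init__(self) -> None:
        S = np.ascontiguousarray(self.S, dtype=np.float64)
        n = len(self.entities)
        if S.shape != (n, n):
            raise DataFormatError(f"similarity shape {S.shape} != ({n}, {n})")
        if S.size:
            if S.min() < -_VALUE_TOL or S.max() > 1 + _VALUE_TOL:
                raise RangeError(
                    f"similarity values outside [0, 1]: min={S.min()}, max={S.max()}"
                )
            if np.abs(S - S.T).max() > 1e-9:
                raise SymmetryError("similarity matrix is asymmetric beyond 1e-9")
            if not np.allclose(np.diag(S), 1.0, atol=1e-9):
                raise DataFormatError("similarity diagonal must be 1")
        object.__setattr__(self, "S", S)


def _read_delimited(path: str | os.PathLike | io.IOBase) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")


def _read_catalog_comments(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read optional ``#drugs:`` / ``#microbes:`` catalog comment lines."""
    out: dict[str, list[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            for key in ("drugs", "microbes"):
                if body.startswith(key + ":"):
                    payload = body[len(key) + 1 :].strip()
                    out[key] = [e for e in payload.split("\t") if e]
    return out


def load_association_table(
    path: str | os.PathLike,
    drug_col: str = "drug",
    microbe_col: str = "microbe",
) -> AssociationDataset:
    """Read a known-association edge list into an :class:`AssociationDataset`.

    Catalogs keep the order of first appearance; duplicate rows collapse to a
    single association. Leading ``#drugs:``/``#microbes:`` comment lines, when
    present, pre-register the full catalogs (so entities with no associations
    survive a save/load round trip).
    """
    try:
        df = _read_delimited(path)
    except (pd.errors.EmptyDataError, csv.Error):
        raise EmptyDatasetError(f"association table {path} is empty") from None
    for col in (drug_col, microbe_col):
        if col not in df.columns:
            raise ConfigurationError(
                f"association table {path} has no column {col!r} "
                f"(found {list(df.columns)})"
            )
    df = df.dropna(subset=[drug_col, microbe_col])
    if df.empty:
        raise EmptyDatasetError(f"association table {path} has no rows")
    drug_ids = [str(d).strip() for d in df[drug_col]]
    microbe_ids = [str(m).strip() for m in df[microbe_col]]

    extra = _read_catalog_comments(path) if isinstance(path, (str, os.PathLike)) else {}
    drugs = EntityCatalog.from_iterable(extra.get("drugs", []) + drug_ids)
    microbes = EntityCatalog.from_iterable(extra.get("microbes", []) + microbe_ids)

    A = np.zeros((len(drugs), len(microbes)), dtype=np.int8)
    for d, m in zip(drug_ids, microbe_ids):
        A[drugs.position(d), microbes.position(m)] = 1
    return AssociationDataset(drugs, microbes, A)


def load_similarity_matrix(
    path: str | os.PathLike,
    expected: EntityCatalog | None = None,
    *,
    fill_missing: float = 0.0,
) -> RawSimilarityMatrix:
    """Read a CSV similarity matrix (identifier header row and first column).

    Mild asymmetry (≤ 1e-6) is symmetrised as ``(S + Sᵀ)/2``; anything larger
    is an error. The diagonal is forced to 1 (self-similarity). When
    *expected* is given, rows/columns are reordered to match it and entities
    missing from the file are filled with *fill_missing* off-diagonal.
    """
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyDatasetError(f"similarity file {path} is empty") from None
    if df.shape[0] != df.shape[1]:
        raise DataFormatError(
            f"similarity file {path} is not square: shape {df.shape}"
        )
    rows = [str(r).strip() for r in df.index]
    cols = [str(c).strip() for c in df.columns]
    if set(rows) != set(cols):
        raise DataFormatError(f"row/column identifier sets differ in {path}")
    # align columns to row order
    df.index = rows
    df.columns = cols
    df = df.loc[rows, rows]
    S = df.to_numpy(dtype=np.float64)
    if S.size:
        if S.min() < -_VALUE_TOL or S.max() > 1 + _VALUE_TOL:
            raise RangeError(
                f"similarity values outside [0, 1] in {path}: "
                f"min={S.min()}, max={S.max()}"
            )
        asym = np.abs(S - S.T).max()
        if asym > _SYMMETRY_TOL:
            raise SymmetryError(f"asymmetry {asym:.3g} > {_SYMMETRY_TOL} in {path}")
        S = (S + S.T) / 2.0
    np.clip(S, 0.0, 1.0, out=S)

    catalog = EntityCatalog.from_iterable(rows)
    if expected is not None:
        full = np.full((len(expected), len(expected)), float(fill_missing))
        present = [e for e in expected if e in catalog]
        idx_exp = np.array([expected.position(e) for e in present], dtype=int)
        idx_src = np.array([catalog.position(e) for e in present], dtype=int)
        if idx_exp.size:
            full[np.ix_(idx_exp, idx_exp)] = S[np.ix_(idx_src, idx_src)]
        S, catalog = full, expected
    np.fill_diagonal(S, 1.0)
    return RawSimilarityMatrix(catalog, S)


def load_side_effects(path: str | os.PathLike) -> SideEffectProfiles:
    """Read a two-column drug/side-effect table into per-drug term sets."""
    profiles: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            return SideEffectProfiles({})
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise DataFormatError(
                    f"malformed side-effect record at {path}:{lineno}: {line!r}"
                )
            drug, term = parts[0].strip(), parts[1].strip()
            profiles.setdefault(drug, set()).add(term)
    return SideEffectProfiles({d: frozenset(t) for d, t in profiles.items()})


def save_dataset(dataset: AssociationDataset, path: str | os.PathLike) -> None:
    """Write the association edge list; catalogs go into comment lines so a
    round trip reproduces the dataset exactly, isolated entities included."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#drugs:\t" + "\t".join(dataset.drugs.ids) + "\n")
        fh.write("#microbes:\t" + "\t".join(dataset.microbes.ids) + "\n")
        fh.write("drug\tmicrobe\n")
        di, mi = np.nonzero(dataset.A)
        for u, v in zip(di, mi):
            fh.write(f"{dataset.drugs.ids[u]}\t{dataset.microbes.ids[v]}\n")


def save_matrix(matrix: RawSimilarityMatrix, path: str | os.PathLike) -> None:
    """Write a similarity matrix as CSV with full float64 precision."""
    df = pd.DataFrame(matrix.S, index=matrix.entities.ids, columns=matrix.entities.ids)
    df.to_csv(path, float_format="%.17g")


def save_side_effects(profiles: SideEffectProfiles, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug\tside_effect\n")
        for drug in sorted(profiles.profiles):
            for term in sorted(profiles.profiles[drug]):
                fh.write(f"{drug}\t{term}\n")


def check_alignment(catalog_a: EntityCatalog, catalog_b: EntityCatalog, what: str) -> None:
    """Raise :class:`AlignmentError` unless both catalogs are identical."""
    if catalog_a.ids != catalog_b.ids:
        raise AlignmentError(f"{what}: entity catalogs differ")
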