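"""Pedigrees and the numerator relationship matrix.

The animal model treats each animal's additive genetic merit as a random
effect whose covariance among animals is proportional to the numerator
relationship matrix A — twice the kinship matrix, with diagonal
``1 + F_i`` where ``F_i`` is the inbreeding coefficient.  A is built here
with the tabular (recursive) method: at herd scale (a few hundred to a
few thousand animals) the dense O(n²) table is trivial, and its inverse,
where needed, is obtained by dense factorisation.

Unknown parents are treated as unrelated, non-inbred founders.
"""

from __future__ import annotations

import graphlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "PedigreeError",
    "read_pedigree",
    "relationship_matrix",
    "inbreeding",
]

#: Tokens accepted as "parent unknown" in pedigree files.
MISSING_TOKENS = {"", "0", "NA", "na", "NaN", "nan", None}


class PedigreeError(ValueError):
    """Raised for structural pedigree defects (cycles, duplicates, ordering)."""


def _is_missing(token) -> bool:
    if token is None:
        return True
    if isinstance(token, float) and np.isnan(token):
        return True
    return str(token).strip() in MISSING_TOKENS


@dataclass(frozen=True)
class Pedigree:
    """An ordered pedigree: ``entries[i] = (animal, sire-or-None, dam-or-None)``.

    Entries are topologically sorted so every parent precedes its
    offspring; founders carry ``None`` for unknown parents.
    """

    entries: tuple[tuple[str, str | None, str | None], ...]

    def __post_init__(self):
        seen: set[str] = set()
        for animal, sire, dam in self.entries:
            if animal in seen:
                raise PedigreeError(f"duplicate animal id {animal!r}")
            for parent in (sire, dam):
                if parent is not None and parent not in seen:
                    raise PedigreeError(
                        f"pedigree not sorted parents-first: parent {parent!r} "
                        f"of {animal!r} appears later or never"
                    )
            seen.add(animal)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def parents_of(self, animal: str) -> tuple[str | None, str | None]:
        for a, s, d in self.entries:
            if a == animal:
                return s, d
        raise KeyError(animal)

    def dam_of(self, animal: str) -> str | None:
        return self.parents_of(animal)[1]


@dataclass(frozen=True)
class RelationshipMatrix:
    """Numerator relationship matrix with its id ordering.

    Invariants: symmetric, positive semidefinite, ``values[i, i] = 1 + F_i``.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "index", {a: i for i, a in enumerate(self.ids)})

    def submatrix(self, ids) -> np.ndarray:
        """Dense A restricted to ``ids`` (marginal relationship structure)."""
        idx = [self.index[a] for a in ids]
        return self.values[np.ix_(idx, idx)]

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.index[a], self.index[b]])


def _normalize_entries(raw_entries):
    """Auto-add undeclared parents as founders and topologically sort."""
    declared = {a for a, _, _ in raw_entries}
    parents_by_animal: dict[str, tuple[str | None, str | None]] = {}
    order: list[str] = []
    for animal, sire, dam in raw_entries:
        if animal in parents_by_animal:
            raise PedigreeError(f"duplicate animal id {animal!r}")
        parents_by_animal[animal] = (sire, dam)
        order.append(animal)
        for parent in (sire, dam):
            if parent is not None and parent not in declared:
                declared.add(parent)
                parents_by_animal[parent] = (None, None)
                order.append(parent)
                warnings.warn(
                    f"parent {parent!r} not declared in pedigree; "
                    "added as unrelated founder",
                    stacklevel=3,
                )
    sorter = graphlib.TopologicalSorter(
        {a: [p for p in parents_by_animal[a] if p is not None] for a in order}
    )
    try:
        topo = list(sorter.static_order())
    except graphlib.CycleError as err:
        cycle = err.args[1]
        raise PedigreeError(
            f"pedigree contains a cycle involving {cycle[0]!r}: "
            + " -> ".join(map(str, cycle))
        ) from err
    return tuple((a, *parents_by_animal[a]) for a in topo)


def pedigree_from_records(records) -> Pedigree:
    """Build a sorted :class:`Pedigree` from (animal, sire, dam) triples.

    Missing parents may be ``None`` or any of the usual missing tokens.
    """
    raw = []
    for animal, sire, dam in records:
        raw.append(
            (
                str(animal),
                None if _is_missing(sire) else str(sire),
                None if _is_missing(dam) else str(dam),
            )
        )
    return Pedigree(_normalize_entries(raw))


def read_pedigree(path) -> Pedigree:
    """Read a delimited pedigree file with columns animal, sire, dam.

    The delimiter (comma or tab) is auto-detected; a header is required.
    Unknown parents are coded "", "0" or "NA".  Parents referenced but
    never declared are appended as founders with a warning; self-parenting
    or longer ancestry cycles raise :class:`PedigreeError`.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        animal_c, sire_c, dam_c = cols["animal"], cols["sire"], cols["dam"]
    except KeyError as err:
        raise PedigreeError(
            f"pedigree file must have animal/sire/dam columns, got {list(df.columns)}"
        ) from err
    return pedigree_from_records(
        df[[animal_c, sire_c, dam_c]].itertuples(index=False, name=None)
    )


def relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    With animals ordered parents-first:

    * ``A[i, j] = 0.5 * (A[j, sire(i)] + A[j, dam(i)])`` for earlier ``j``,
      with unknown-parent terms contributing 0;
    * ``A[i, i] = 1 + 0.5 * A[sire(i), dam(i)]`` (1 if either is unknown).
    """
    n = len(ped)
    ids = ped.ids
    index = {a: i for i, a in enumerate(ids)}
    A = np.zeros((n, n))
    for i, (animal, sire, dam) in enumerate(ped.entries):
        s = index[sire] if sire is not None else None
        d = index[dam] if dam is not None else None
        if i:
            row = np.zeros(i)
            if s is not None:
                row += A[:i, s]
            if d is not None:
                row += A[:i, d]
            A[:i, i] = A[i, :i] = 0.5 * row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s is not None and d is not None else 0.0)
    return RelationshipMatrix(ids, A)


def inbreeding(A: RelationshipMatrix) -> pd.Series:
    """Inbreeding coefficients ``F_i = A[i, i] - 1`` per animal."""
    return pd.Series(np.diag(A.values) - 1.0, index=list(A.ids), name="F")
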