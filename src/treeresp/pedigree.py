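"""Pedigree representation, additive relationship matrix, family structure.

The pedigree dialect is a 3-column CSV with header ``id,sire,dam``; ``0`` or
an empty field means an unknown parent.  Unknown parents are treated as
unique, unrelated, non-inbred founders (the standard tabular-method
convention), which is also how externally-sired offspring enter the
relationship matrix: their sire is simply recorded as unknown and the
individual carries an ``external`` flag.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: sentinel for an unknown parent in the Python API
UNKNOWN = None

_UNKNOWN_TOKENS = {"", "0", "na", "nan", "none"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, orphan parent, duplicate id)."""


@dataclass
class Pedigree:
    """A validated, topologically ordered pedigree.

    ``records`` is a tuple of ``(individual, sire, dam)`` triples where a
    parent is either an individual id appearing earlier in ``records`` or
    :data:`UNKNOWN`.  ``external_sired`` flags offspring whose true father is
    outside the base population (pollen contamination); such sires are stored
    as :data:`UNKNOWN`.
    """

    records: tuple
    external_sired: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self._index = {rec[0]: i for i, rec in enumerate(self.records)}

    # -- basic accessors ---------------------------------------------------
    @property
    def ids(self) -> tuple:
        return tuple(rec[0] for rec in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, individual) -> bool:
        return individual in self._index

    def index_of(self, individual) -> int:
        return self._index[individual]

    def parents(self, individual):
        _, sire, dam = self.records[self._index[individual]]
        return sire, dam

    @property
    def founders(self) -> frozenset:
        """Individuals with both parents unknown."""
        return frozenset(r[0] for r in self.records if r[1] is None and r[2] is None)

    @property
    def offspring_ids(self) -> tuple:
        """Individuals with at least one known parent."""
        return tuple(r[0] for r in self.records if r[1] is not None or r[2] is not None)

    def drop(self, individual) -> "Pedigree":
        """Return a pedigree without ``individual`` (must be childless)."""
        for rec in self.records:
            if individual in rec[1:]:
                raise PedigreeError(f"cannot drop {individual!r}: it has offspring")
        return Pedigree(
            tuple(r for r in self.records if r[0] != individual),
            self.external_sired - {individual},
        )


@dataclass
class RelationshipMatrix:
    """Average numerator relationship matrix, ordered like its pedigree."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.ids)}

    def loc(self, i, j) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def submatrix(self, ids: Sequence) -> np.ndarray:
        idx = [self._index[i] for i in ids]
        return self.values[np.ix_(idx, idx)]

    def to_dense_csv(self, path) -> None:
        pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids)).to_csv(
            path, index_label="id"
        )

    def to_triplet_csv(self, path, tol: float = 0.0) -> None:
        """Write nonzero upper-triangle entries as ``i,j,value`` rows."""
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i, n):
                v = self.values[i, j]
                if abs(v) > tol:
                    rows.append((self.ids[i], self.ids[j], v))
        pd.DataFrame(rows, columns=["i", "j", "value"]).to_csv(path, index=False)


@dataclass
class FamilyStructure:
    """Half-sib and full-sib family maps derived from a pedigree.

    ``half_sib`` maps each known parent to its offspring (an offspring with
    two known parents is counted once per parent).  ``full_sib`` maps each
    unordered (sire, dam) pair to the offspring having exactly those two
    known parents; offspring with an unknown parent appear only in the known
    parent's half-sib family.
    """

    half_sib: Mapping
    full_sib: Mapping

    @property
    def n_fullsib_families(self) -> int:
        return len(self.full_sib)

    def half_sib_sizes(self) -> dict:
        return {p: len(o) for p, o in self.half_sib.items()}


# ---------------------------------------------------------------------------
# validation


def validate_pedigree(
    records: Iterable, external_sired: Iterable = ()
) -> Pedigree:
    """Validate raw ``(id, sire, dam)`` triples and return an ordered Pedigree.

    Raises :class:`PedigreeError` for duplicate ids, references to undeclared
    parents, or cycles (an individual being its own ancestor).
    """
    records = [(r[0], r[1], r[2]) for r in records]
    if not records:
        raise PedigreeError("empty pedigree")

    seen = set()
    for ind, _, _ in records:
        if ind in seen:
            raise PedigreeError(f"duplicate individual id {ind!r}")
        seen.add(ind)

    orphans = sorted(
        {p for _, s, d in records for p in (s, d) if p is not None and p not in seen}
    )
    if orphans:
        raise PedigreeError(
            "unknown parent " + ", ".join(str(p) for p in orphans)
        )

    # Kahn topological sort on the parent -> offspring DAG, stable in input order
    by_id = {r[0]: r for r in records}
    n_pending = {r[0]: sum(p is not None for p in r[1:]) for r in records}
    children = defaultdict(list)
    for ind, s, d in records:
        for p in {s, d} - {None}:
            children[p].append(ind)
    queue = deque(r[0] for r in records if n_pending[r[0]] == 0)
    ordered = []
    while queue:
        ind = queue.popleft()
        ordered.append(by_id[ind])
        for child in children[ind]:
            n_pending[child] -= 1
            if n_pending[child] == 0:
                queue.append(child)
    if len(ordered) != len(records):
        cyclic = sorted(i for i, n in n_pending.items() if n > 0)
        raise PedigreeError(f"cycle detected involving {', '.join(map(str, cyclic))}")

    return Pedigree(tuple(ordered), frozenset(external_sired))


# ---------------------------------------------------------------------------
# CSV dialect


def _parse_parent(token) -> Optional[str]:
    if token is None:
        return None
    tok = str(token).strip()
    return None if tok.lower() in _UNKNOWN_TOKENS else tok


def read_pedigree_csv(path) -> Pedigree:
    """Read the 3-column ``id,sire,dam`` dialect (0/empty = unknown)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree CSV must have columns {sorted(required)}")
    records = [
        (row["id"].strip(), _parse_parent(row["sire"]), _parse_parent(row["dam"]))
        for _, row in df.iterrows()
    ]
    external = (
        frozenset(df.loc[df["external"].astype(str) == "1", "id"].str.strip())
        if "external" in df.columns
        else frozenset()
    )
    return validate_pedigree(records, external)


def write_pedigree_csv(ped: Pedigree, path) -> None:
    rows = [
        {
            "id": ind,
            "sire": "0" if s is None else s,
            "dam": "0" if d is None else d,
            "external": "1" if ind in ped.external_sired else "0",
        }
        for ind, s, d in ped.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# relationship matrix (tabular method)


def numerator_relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Compute A by the tabular method.

    ``a_ii = 1 + 0.5 * a(sire, dam)`` (1 if either parent unknown) and
    ``a_ij = 0.5 * (a(j, sire_i) + a(j, dam_i))`` with unknown-parent terms 0.
    """
    n = len(ped)
    idx = {ind: i for i, ind in enumerate(ped.ids)}
    A = np.zeros((n, n))
    for i, (ind, sire, dam) in enumerate(ped.records):
        si = idx[sire] if sire is not None else -1
        di = idx[dam] if dam is not None else -1
        row = np.zeros(n)
        if si >= 0:
            row += 0.5 * A[si]
        if di >= 0:
            row += 0.5 * A[di]
        A[i, :] = row
        A[:, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    return RelationshipMatrix(ped.ids, A)


# ---------------------------------------------------------------------------
# families


def assemble_families(ped: Pedigree) -> FamilyStructure:
    """Group offspring into half-sib (per parent) and full-sib families.

    Parent pairs are unordered.  Offspring with one unknown parent join only
    the known parent's half-sib family and no full-sib family.
    """
    half = defaultdict(list)
    full = defaultdict(list)
    for ind, sire, dam in ped.records:
        if sire is None and dam is None:
            continue
        for p in (sire, dam):
            if p is not None:
                half[p].append(ind)
        if sire is not None and dam is not None:
            full[tuple(sorted((sire, dam)))].append(ind)
    return FamilyStructure(dict(half), dict(full))


def diallel_coverage(n_parents: int, n_fullsib_families: int) -> float:
    """Fraction of the half-diallel (selfs excluded) realized by the data."""
    if n_parents < 2:
        raise ValueError("need at least 2 parents")
    possible = n_parents * (n_parents - 1) // 2
    if n_fullsib_families < 0 or n_fullsib_families > possible:
        raise ValueError(
            f"{n_fullsib_families} full-sib families exceeds the "
            f"{possible} possible crosses among {n_parents} parents"
        )
    return n_fullsib_families / possible
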