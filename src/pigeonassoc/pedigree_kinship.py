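"""Pedigrees and the additive (numerator) relationship matrix.

The additive relationship matrix A holds, for every pair of animals, twice
their coefficient of coancestry: the expected fraction of alleles shared
identical by descent.  It is built by the tabular method over a topologically
ordered pedigree:

    a(i,i) = 1 + a(sire_i, dam_i) / 2
    a(i,j) = (a(j, sire_i) + a(j, dam_i)) / 2     for j ordered before i,

with missing-parent terms dropped (unknown parents are unrelated, non-inbred
founders).  sigma2_a * A is the covariance of the polygenic effect in the
animal model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass(frozen=True)
class PedigreeEntry:
    animal_id: str
    sire_id: Optional[str] = None
    dam_id: Optional[str] = None
    sex: Optional[str] = None


class Pedigree:
    """A validated set of parent links.

    Every referenced sire/dam must itself be an entry (or unknown/None);
    parental sexes, where recorded, must be consistent with their role.
    """

    def __init__(self, entries: Iterable[PedigreeEntry]):
        self.entries: list[PedigreeEntry] = list(entries)
        ids = [e.animal_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate animal ids in pedigree: {dupes}")
        self._by_id = {e.animal_id: e for e in self.entries}
        for e in self.entries:
            for parent, role, sex in ((e.sire_id, "sire", "male"), (e.dam_id, "dam", "female")):
                if parent is None:
                    continue
                if parent not in self._by_id:
                    raise InputError(
                        f"animal {e.animal_id!r} references unknown {role} {parent!r}"
                    )
                psex = self._by_id[parent].sex
                if psex is not None and psex != sex:
                    raise InputError(
                        f"{role} {parent!r} of {e.animal_id!r} is recorded as {psex}"
                    )

    @property
    def ids(self) -> list[str]:
        return [e.animal_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, animal_id: str) -> PedigreeEntry:
        return self._by_id[animal_id]

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._by_id

    def parents(self, animal_id: str) -> tuple[Optional[str], Optional[str]]:
        e = self._by_id[animal_id]
        return e.sire_id, e.dam_id

    def is_sorted(self) -> bool:
        """True iff every parent precedes all its offspring."""
        seen: set[str] = set()
        for e in self.entries:
            for p in (e.sire_id, e.dam_id):
                if p is not None and p not in seen:
                    return False
            seen.add(e.animal_id)
        return True

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": [e.animal_id for e in self.entries],
                "sire_id": [e.sire_id for e in self.entries],
                "dam_id": [e.dam_id for e in self.entries],
                "sex": [e.sex for e in self.entries],
            }
        )


def _find_cycle(ped: Pedigree) -> list[str]:
    """Return one parentage cycle (for the error message)."""
    WHITE, GREY, BLACK = 0, 1, 2
    color = dict.fromkeys(ped.ids, WHITE)
    parent_of = {e.animal_id: [p for p in (e.sire_id, e.dam_id) if p] for e in ped.entries}

    def dfs(node: str, path: list[str]) -> Optional[list[str]]:
        color[node] = GREY
        path.append(node)
        for p in parent_of[node]:
            if color[p] == GREY:
                return path[path.index(p):] + [p]
            if color[p] == WHITE:
                cyc = dfs(p, path)
                if cyc:
                    return cyc
        path.pop()
        color[node] = BLACK
        return None

    for start in ped.ids:
        if color[start] == WHITE:
            cyc = dfs(start, [])
            if cyc:
                return cyc
    return []


def topological_sort(ped: Pedigree) -> Pedigree:
    """Reorder entries so every parent precedes all its offspring (Kahn)."""
    remaining = {e.animal_id: {p for p in (e.sire_id, e.dam_id) if p} for e in ped.entries}
    order: list[PedigreeEntry] = []
    placed: set[str] = set()
    # stable: repeatedly take, in input order, animals whose parents are placed
    pending = list(ped.entries)
    while pending:
        progress = []
        rest = []
        for e in pending:
            if remaining[e.animal_id] <= placed:
                progress.append(e)
            else:
                rest.append(e)
        if not progress:
            cycle = _find_cycle(ped)
            raise InputError(f"pedigree contains a parentage cycle: {' -> '.join(cycle)}")
        for e in progress:
            order.append(e)
            placed.add(e.animal_id)
        pending = rest
    return Pedigree(order)


def truncate_pedigree(ped: Pedigree, focal_ids: Sequence[str], generations: int = 3) -> Pedigree:
    """Keep focal animals plus ancestors within ``generations`` meioses.

    Depth is the minimum number of meioses from any focal animal.  Animals at
    the depth limit lose their parent links and become founders; everything
    deeper is dropped.
    """
    if generations < 0:
        raise InputError("generations must be >= 0")
    unknown = [f for f in focal_ids if f not in ped]
    if unknown:
        raise InputError(f"focal ids not in pedigree: {sorted(unknown)}")

    depth: dict[str, int] = {}
    frontier = list(dict.fromkeys(focal_ids))
    for f in frontier:
        depth[f] = 0
    while frontier:
        nxt = []
        for a in frontier:
            d = depth[a]
            if d == generations:
                continue
            for p in ped.parents(a):
                if p is not None and depth.get(p, generations + 1) > d + 1:
                    depth[p] = d + 1
                    nxt.append(p)
        frontier = nxt

    kept = set(depth)
    entries = []
    for e in ped.entries:
        if e.animal_id not in kept:
            continue
        if depth[e.animal_id] == generations:
            entries.append(PedigreeEntry(e.animal_id, None, None, e.sex))
        else:
            sire = e.sire_id if e.sire_id in kept else None
            dam = e.dam_id if e.dam_id in kept else None
            entries.append(PedigreeEntry(e.animal_id, sire, dam, e.sex))
    return Pedigree(entries)


@dataclass
class RelationshipMatrix:
    """Additive relationship coefficients, indexed by animal id."""

    ids: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise InputError("relationship matrix shape does not match id list")
        self._index = {a: i for i, a in enumerate(self.ids)}

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        missing = [i for i in ids if i not in self._index]
        if missing:
            raise InputError(f"animals not in relationship matrix: {sorted(missing)}")
        idx = [self._index[i] for i in ids]
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def inbreeding(self) -> pd.Series:
        """Inbreeding coefficients F = diag(A) - 1."""
        return pd.Series(np.diag(self.values) - 1.0, index=self.ids)


def additive_relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Tabular-method additive relationship matrix over the whole pedigree.

    Requires a topologically ordered pedigree (parents before offspring);
    unknown parents contribute nothing to the recursion.
    """
    if not ped.is_sorted():
        raise InputError(
            "pedigree is not topologically ordered; call topological_sort first"
        )
    ids = ped.ids
    n = len(ids)
    index = {a: i for i, a in enumerate(ids)}
    A = np.zeros((n, n))
    for i, e in enumerate(ped.entries):
        s = index.get(e.sire_id) if e.sire_id else None
        d = index.get(e.dam_id) if e.dam_id else None
        for j in range(i):
            a_js = A[j, s] if s is not None else 0.0
            a_jd = A[j, d] if d is not None else 0.0
            A[i, j] = A[j, i] = 0.5 * (a_js + a_jd)
        a_sd = A[s, d] if (s is not None and d is not None) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
    return RelationshipMatrix(ids, A)
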