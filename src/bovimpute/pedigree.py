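"""Pedigree container: ordered parent records with generation indices.

A pedigree is a list of (id, sire, dam) records. Unknown parents are coded as
``None`` (files use "0" or an empty field). Records are stored topologically
ordered so that parents always precede offspring, which is the order every
recursive computation (tabular relationship matrix, gene dropping) requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Optional, Sequence

import numpy as np

from ._errors import PedigreeError

UNKNOWN = None


@dataclass(frozen=True)
class PedigreeRecord:
    id: str
    sire: Optional[str]
    dam: Optional[str]
    generation: int
    sex: Optional[str] = None  # "M"/"F" when the simulator produced the record


class Pedigree:
    """Topologically ordered pedigree.

    Parameters
    ----------
    records
        Records already ordered parents-before-offspring with generation
        indices assigned. Use :meth:`from_records` to build from raw
        (id, sire, dam) triples.
    """

    def __init__(self, records: Sequence[PedigreeRecord]):
        self.records = list(records)
        self._index = {r.id: i for i, r in enumerate(self.records)}
        if len(self._index) != len(self.records):
            raise PedigreeError("duplicate individual id in pedigree")
        for r in self.records:
            for parent in (r.sire, r.dam):
                if parent is not None and self._index[parent] >= self._index[r.id]:
                    raise PedigreeError(f"parent {parent} does not precede offspring {r.id}")

    @classmethod
    def from_records(
        cls,
        triples: Iterable[tuple],
        sexes: Optional[dict] = None,
    ) -> "Pedigree":
        """Build a pedigree from (id, sire, dam) triples in any order.

        "0", "" and None all denote an unknown parent. Parents referenced but
        never listed as individuals are added as founders.
        """
        norm = lambda v: None if v in (None, "", "0", 0) else str(v)
        raw = []
        seen = set()
        for t in triples:
            iid, sire, dam = str(t[0]), norm(t[1]), norm(t[2])
            if iid in seen:
                raise PedigreeError(f"duplicate individual id {iid!r}")
            seen.add(iid)
            raw.append((iid, sire, dam))
        parents_only = []
        for _, sire, dam in raw:
            for p in (sire, dam):
                if p is not None and p not in seen:
                    seen.add(p)
                    parents_only.append((p, None, None))
        raw = parents_only + raw
        graph = {iid: [p for p in (sire, dam) if p is not None] for iid, sire, dam in raw}
        try:
            order = list(TopologicalSorter(graph).static_order())
        except CycleError as exc:
            raise PedigreeError(f"pedigree contains a cycle: {exc.args[1]}") from exc
        by_id = {iid: (sire, dam) for iid, sire, dam in raw}
        sexes = sexes or {}
        gen: dict[str, int] = {}
        records = []
        for iid in order:
            sire, dam = by_id[iid]
            g = 0
            for p in (sire, dam):
                if p is not None:
                    g = max(g, gen[p] + 1)
            gen[iid] = g
            records.append(PedigreeRecord(iid, sire, dam, g, sexes.get(iid)))
        return cls(records)

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def __getitem__(self, iid: str) -> PedigreeRecord:
        return self.records[self._index[iid]]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    @property
    def founders(self) -> list[str]:
        return [r.id for r in self.records if r.sire is None and r.dam is None]

    def generation_of(self, iid: str) -> int:
        return self.records[self._index[iid]].generation

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire and dam row indices per record; -1 marks an unknown parent."""
        n = len(self.records)
        sire = np.full(n, -1, dtype=np.int64)
        dam = np.full(n, -1, dtype=np.int64)
        for i, r in enumerate(self.records):
            if r.sire is not None:
                sire[i] = self._index[r.sire]
            if r.dam is not None:
                dam[i] = self._index[r.dam]
        return sire, dam
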