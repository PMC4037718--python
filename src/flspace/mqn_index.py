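"""Exact nearest-neighbour engine over MQN space.

Entries are bucketed by the sum of their 42 MQN values.  Because
``|sum(a) - sum(b)| <= CBD(a, b)`` (the L1 ball projects onto the sum axis),
a range query with boundary ``d_max`` only needs to inspect buckets whose
sum lies within ``d_max`` of the query's sum — the hash never discards a
true hit, so results are exact, not approximate.

Each entry carries a database-membership bit mask; a query's *wanted* mask
(bitwise OR of the chosen databases) keeps entries with a non-zero AND.
Optional locks restrict hits to isomers of the query (identical Hill
formula) and/or to entries with the query's H-bond donor / acceptor atom
counts — constraints that preserve the functional-group character of hits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.base import BaseEstimator

from . import mqn as _mqn
from .molio import MoleculeRecord, hill_formula, record_from_smiles

DEFAULT_D_MAX = 12
MAX_DATABASES = 64
FORMAT_VERSION = 1

_HBA_IDX = _mqn.MQN_NAMES.index("hba")
_HBD_IDX = _mqn.MQN_NAMES.index("hbd")


@dataclass
class SearchQuery:
    """A range/kNN search request against an :class:`MQNNeighborIndex`."""

    query: object  # MoleculeRecord | Chem.Mol | SMILES str | MQN vector
    d_max: int | None = DEFAULT_D_MAX
    wanted_mask: int | None = None  # None = all registered databases
    isomers_only: bool = False
    lock_hbd: bool = False
    lock_hba: bool = False

    def __post_init__(self):
        if self.d_max is not None and self.d_max < 0:
            raise ValueError("d_max must be >= 0")
        if self.wanted_mask == 0:
            raise ValueError("wanted_mask must not be 0 (no database selected)")


@dataclass
class _ResolvedQuery:
    vector: np.ndarray
    formula: str | None
    hbd: int
    hba: int


class MQNNeighborIndex(BaseEstimator):
    """Sum-hashed exact CBD search index over a molecule library.

    Parameters
    ----------
    default_db : str
        Database name assigned to records without an explicit assignment,
        so every entry's mask has at least one bit set.
    ionize : bool
        Ionize molecules at pH 7.4 before computing their MQN vector.

    Fitted attributes (trailing underscore) hold the entry table:
    ``ids_``, ``vectors_`` (n, 42), ``masks_``, ``formulas_``, ``hba_``,
    ``hbd_``, ``sums_``, ``buckets_`` (sum -> row indices) and
    ``db_registry_`` (database name -> bit position).
    """

    def __init__(self, default_db: str = "library", ionize: bool = True):
        self.default_db = default_db
        self.ionize = ionize

    # -- construction ------------------------------------------------------

    def fit(
        self,
        records: Sequence[MoleculeRecord],
        db_assignments: Mapping[str, Iterable[str]] | None = None,
        db_registry: Mapping[str, int] | None = None,
    ) -> "MQNNeighborIndex":
        """Build the index from deduplicated records.

        ``db_assignments`` maps record id -> iterable of database names;
        unassigned records go to ``default_db``.  A fixed ``db_registry``
        (name -> bit) may be supplied; otherwise bits are assigned to the
        sorted set of names encountered.
        """
        db_assignments = dict(db_assignments or {})

        names = {self.default_db}
        for dbs in db_assignments.values():
            names.update(dbs)
        if db_registry is not None:
            registry = dict(db_registry)
            unknown = names - set(registry)
            unknown.discard(self.default_db)
            if unknown and not all(n in registry for n in names if n != self.default_db):
                raise ValueError(f"unregistered database name(s): {sorted(unknown)}")
            if self.default_db not in registry:
                registry[self.default_db] = max(registry.values(), default=-1) + 1
        else:
            registry = {name: bit for bit, name in enumerate(sorted(names))}
        if len(registry) > MAX_DATABASES:
            raise ValueError(f"more than {MAX_DATABASES} databases")
        if len(set(registry.values())) != len(registry):
            raise ValueError("db_registry bit positions must be unique")

        ids: list[str] = []
        vectors: list[np.ndarray] = []
        masks: list[int] = []
        formulas: list[str] = []
        seen: set[str] = set()
        for rec in records:
            if rec.id in seen:
                raise ValueError(f"duplicate id in index input: {rec.id!r}")
            seen.add(rec.id)
            mask = 0
            for db in db_assignments.get(rec.id, (self.default_db,)):
                if db not in registry:
                    raise ValueError(f"unregistered database name: {db!r}")
                mask |= 1 << registry[db]
            if mask == 0:
                mask = 1 << registry[self.default_db]
            ids.append(rec.id)
            vectors.append(_mqn.compute_mqn(rec.mol, ionize=self.ionize))
            masks.append(mask)
            formulas.append(rec.formula)

        self.db_registry_ = registry
        self.ids_ = np.asarray(ids, dtype=object)
        self.vectors_ = (
            np.vstack(vectors) if vectors else np.zeros((0, _mqn.N_MQN), dtype=np.int64)
        )
        self.masks_ = np.asarray(masks, dtype=np.uint64)
        self.formulas_ = np.asarray(formulas, dtype=object)
        self.hba_ = self.vectors_[:, _HBA_IDX] if len(ids) else np.zeros(0, int)
        self.hbd_ = self.vectors_[:, _HBD_IDX] if len(ids) else np.zeros(0, int)
        self.sums_ = self.vectors_.sum(axis=1)
        buckets: dict[int, list[int]] = {}
        for row, s in enumerate(self.sums_):
            buckets.setdefault(int(s), []).append(row)
        self.buckets_ = {s: np.asarray(rows) for s, rows in buckets.items()}
        return self

    @property
    def n_entries_(self) -> int:
        return len(self.ids_)

    def full_mask(self) -> int:
        mask = 0
        for bit in self.db_registry_.values():
            mask |= 1 << bit
        return mask

    def mask_for(self, db_names: Iterable[str]) -> int:
        """Wanted bit mask for a database selection (bitwise OR of their bits)."""
        mask = 0
        for name in db_names:
            if name not in self.db_registry_:
                raise ValueError(f"unknown database {name!r}")
            mask |= 1 << self.db_registry_[name]
        return mask

    # -- queries -----------------------------------------------------------

    def _resolve(self, query) -> _ResolvedQuery:
        if isinstance(query, SearchQuery):
            raise TypeError("pass the SearchQuery to search(), not _resolve")
        if isinstance(query, MoleculeRecord):
            vec = _mqn.compute_mqn(query.mol, ionize=self.ionize)
            formula = query.formula
        elif isinstance(query, Chem.Mol):
            vec = _mqn.compute_mqn(query, ionize=self.ionize)
            formula = hill_formula(query)
        elif isinstance(query, str):
            rec = record_from_smiles(query, "query")
            if rec is None:
                raise ValueError(f"unparsable query SMILES: {query!r}")
            vec = _mqn.compute_mqn(rec.mol, ionize=self.ionize)
            formula = rec.formula
        else:
            vec = np.asarray(query, dtype=np.int64)
            if vec.shape != (_mqn.N_MQN,):
                raise ValueError("query vector must have length 42")
            formula = None
        return _ResolvedQuery(
            vector=vec,
            formula=formula,
            hbd=int(vec[_HBD_IDX]),
            hba=int(vec[_HBA_IDX]),
        )

    def _candidate_rows(self, qsum: int, d_max: int | None) -> np.ndarray:
        if d_max is None:
            return np.arange(self.n_entries_)
        rows = [
            self.buckets_[s]
            for s in range(qsum - d_max, qsum + d_max + 1)
            if s in self.buckets_
        ]
        if not rows:
            return np.zeros(0, dtype=int)
        return np.concatenate(rows)

    def search(self, q: SearchQuery) -> list[tuple[str, int]]:
        """Range search: all entries within ``q.d_max``, ascending by (cbd, id)."""
        rq = self._resolve(q.query)
        wanted = q.wanted_mask if q.wanted_mask is not None else self.full_mask()
        if wanted == 0:
            raise ValueError("wanted_mask must not be 0")
        if q.isomers_only and rq.formula is None:
            raise ValueError("isomer lock requires a molecular query, not a raw vector")

        rows = self._candidate_rows(int(rq.vector.sum()), q.d_max)
        if rows.size == 0:
            return []
        dists = _mqn.cbd_matrix(rq.vector, self.vectors_[rows])
        keep = np.ones(rows.size, dtype=bool)
        if q.d_max is not None:
            keep &= dists <= q.d_max
        keep &= (self.masks_[rows] & np.uint64(wanted)) != 0
        if q.isomers_only:
            keep &= self.formulas_[rows] == rq.formula
        if q.lock_hbd:
            keep &= self.hbd_[rows] == rq.hbd
        if q.lock_hba:
            keep &= self.hba_[rows] == rq.hba
        hits = [(self.ids_[r], int(d)) for r, d in zip(rows[keep], dists[keep])]
        hits.sort(key=lambda t: (t[1], t[0]))
        return hits

    def range_search(
        self,
        query,
        d_max: int | None = DEFAULT_D_MAX,
        dbs: Iterable[str] | None = None,
        isomers_only: bool = False,
        lock_hbd: bool = False,
        lock_hba: bool = False,
    ) -> list[tuple[str, int]]:
        mask = self.mask_for(dbs) if dbs is not None else None
        return self.search(
            SearchQuery(query, d_max, mask, isomers_only, lock_hbd, lock_hba)
        )

    def knn_search(
        self,
        query,
        k: int,
        dbs: Iterable[str] | None = None,
        isomers_only: bool = False,
        lock_hbd: bool = False,
        lock_hba: bool = False,
    ) -> list[tuple[str, int]]:
        """The k nearest entries under the constraints (expanding-ring wrapper).

        Returns fewer than k only when the constrained library is smaller.
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        d = 4
        max_spread = int(self.sums_.max() - self.sums_.min()) if self.n_entries_ else 0
        while True:
            hits = self.range_search(
                query, d, dbs, isomers_only, lock_hbd, lock_hba
            )
            if len(hits) >= k and hits[k - 1][1] <= d:
                return hits[:k]
            if d > max_spread:  # buckets exhausted: do the unbounded scan
                hits = self.range_search(
                    query, None, dbs, isomers_only, lock_hbd, lock_hba
                )
                return hits[:k]
            d *= 2

    # -- serialization (JSON header + TSV entry table) ----------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        table = pd.DataFrame(
            {
                "id": self.ids_,
                "formula": self.formulas_,
                "mask": self.masks_.astype(np.uint64),
            }
        )
        for j, name in enumerate(_mqn.MQN_NAMES):
            table[name] = self.vectors_[:, j]
        tsv_path = path.with_suffix(path.suffix + ".tsv")
        table.to_csv(tsv_path, sep="\t", index=False)
        header = {
            "format_version": FORMAT_VERSION,
            "db_registry": self.db_registry_,
            "default_db": self.default_db,
            "ionize": self.ionize,
            "n_entries": int(self.n_entries_),
            "entry_table": tsv_path.name,
        }
        path.write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MQNNeighborIndex":
        path = Path(path)
        header = json.loads(path.read_text())
        if header.get("format_version") != FORMAT_VERSION:
            raise ValueError("unsupported index format version")
        table = pd.read_csv(path.parent / header["entry_table"], sep="\t")
        idx = cls(default_db=header["default_db"], ionize=header["ionize"])
        idx.db_registry_ = {k: int(v) for k, v in header["db_registry"].items()}
        idx.ids_ = table["id"].astype(str).to_numpy(dtype=object)
        idx.formulas_ = table["formula"].astype(str).to_numpy(dtype=object)
        idx.masks_ = table["mask"].to_numpy(dtype=np.uint64)
        idx.vectors_ = table[list(_mqn.MQN_NAMES)].to_numpy(dtype=np.int64)
        idx.hba_ = idx.vectors_[:, _HBA_IDX]
        idx.hbd_ = idx.vectors_[:, _HBD_IDX]
        idx.sums_ = idx.vectors_.sum(axis=1)
        buckets: dict[int, list[int]] = {}
        for row, s in enumerate(idx.sums_):
            buckets.setdefault(int(s), []).append(row)
        idx.buckets_ = {s: np.asarray(rows) for s, rows in buckets.items()}
        return idx


def build_index(
    records: Sequence[MoleculeRecord],
    db_assignments: Mapping[str, Iterable[str]] | None = None,
    **kwargs,
) -> MQNNeighborIndex:
    """Functional wrapper over :meth:`MQNNeighborIndex.fit`."""
    return MQNNeighborIndex(**kwargs).fit(records, db_assignments)


def brute_force_search(
    index: MQNNeighborIndex,
    query,
    d_max: int | None = DEFAULT_D_MAX,
    dbs: Iterable[str] | None = None,
    isomers_only: bool = False,
    lock_hbd: bool = False,
    lock_hba: bool = False,
) -> list[tuple[str, int]]:
    """Reference linear scan over every entry, ignoring the sum hash.

    Used as the correctness oracle for :meth:`search`; applies the same
    constraints entry by entry.
    """
    rq = index._resolve(query)
    wanted = index.mask_for(dbs) if dbs is not None else index.full_mask()
    hits = []
    for row in range(index.n_entries_):
        d = _mqn.cbd(rq.vector, index.vectors_[row])
        if d_max is not None and d > d_max:
            continue
        if not (int(index.masks_[row]) & wanted):
            continue
        if isomers_only and index.formulas_[row] != rq.formula:
            continue
        if lock_hbd and index.hbd_[row] != rq.hbd:
            continue
        if lock_hba and index.hba_[row] != rq.hba:
            continue
        hits.append((index.ids_[row], int(d)))
    hits.sort(key=lambda t: (t[1], t[0]))
    return hits
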