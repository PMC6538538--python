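"""Concept / relation data model, dated knowledge snapshots, and readers.

The pipeline consumes two dialects of subject--relation--object triple
stores: a pipe-delimited thesaurus-style format (one relation instance per
row, no header, configurable column positions) and a predication-table
format (delimited rows with a header naming ``subject_cui``, ``predicate``
and ``object_cui``, as emitted by automatic relation extractors).  Both are
reduced to the same in-memory representation: :class:`RelationTriple` sets
aggregated by (subject, predicate, object) identity, plus a concept ->
semantic-type mapping.

Hierarchical ``ISA`` relations are collapsed before discovery: concepts
connected by ISA form an equivalence class represented by the
lexicographically smallest member, all other triples are rewritten onto the
representatives, and the resulting self-loops are dropped.  Without this
step, trivially inferable variants (a disease and its parent phenomenon)
would dominate the proposed hidden knowledge.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError

log = logging.getLogger(__name__)

__all__ = [
    "Concept",
    "RelationTriple",
    "KnowledgeSnapshot",
    "SemanticTypeInventory",
    "RRFDialect",
    "read_rrf_relations",
    "read_predications",
    "read_semtypes",
    "write_rrf_relations",
    "write_semtypes",
    "merge_isa_classes",
    "merge_semtype_map",
    "build_snapshot",
]


@dataclass(frozen=True)
class Concept:
    """A vocabulary concept (CUI-like identifier plus its semantic types)."""

    id: str
    semtypes: frozenset[str]
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.semtypes:
            raise DataError(f"concept {self.id!r} has no semantic types")


@dataclass(frozen=True, order=True)
class RelationTriple:
    """One directed subject--predicate--object assertion with a frequency.

    ``count`` is the number of source rows (provenance records) asserting
    the triple; identity for aggregation is (subject, predicate, object).
    ``negated`` marks predicates that deny rather than assert the relation
    (e.g. ``NEG_TREATS``); the filtering stage drops them by default.
    """

    subject: str
    predicate: str
    object: str
    count: int = 1
    negated: bool = field(default=False, compare=False)

    def key(self) -> tuple[str, str, str]:
        return (self.subject, self.predicate, self.object)


def aggregate_triples(triples: Iterable[RelationTriple]) -> list[RelationTriple]:
    """Merge duplicate (subject, predicate, object) rows, summing counts."""
    merged: dict[tuple[str, str, str], RelationTriple] = {}
    for t in triples:
        prev = merged.get(t.key())
        if prev is None:
            merged[t.key()] = t
        else:
            merged[t.key()] = replace(prev, count=prev.count + t.count)
    return sorted(merged.values())


class SemanticTypeInventory:
    """Ordered inventory of semantic-type identifiers.

    Ordering is lexicographic so that feature layouts derived from the
    inventory are reproducible regardless of input row order.
    """

    def __init__(self, types: Iterable[str]):
        self.types: tuple[str, ...] = tuple(sorted(set(types)))
        self.index: dict[str, int] = {t: i for i, t in enumerate(self.types)}

    def __len__(self) -> int:
        return len(self.types)

    def __contains__(self, t: str) -> bool:
        return t in self.index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SemanticTypeInventory) and self.types == other.types


class KnowledgeSnapshot:
    """A dated store of relation triples with adjacency queries.

    Snapshots are immutable; filters produce new snapshots via
    :meth:`replace_triples`.  Concepts are restricted to triple endpoints so
    the concept set, the relation inventory and the adjacency structure
    always describe the same graph.
    """

    def __init__(
        self,
        date_label: str,
        concepts: Mapping[str, Concept],
        triples: Sequence[RelationTriple],
    ):
        self.date_label = date_label
        self.triples: tuple[RelationTriple, ...] = tuple(sorted(triples))
        self.concepts: dict[str, Concept] = dict(concepts)
        for t in self.triples:
            if t.subject not in self.concepts or t.object not in self.concepts:
                raise DataError(
                    f"triple {t.key()} references a concept missing from the "
                    f"snapshot {date_label!r}"
                )
        self._out: dict[str, dict[str, list[RelationTriple]]] = {}
        self._in: dict[str, set[str]] = {}
        for t in self.triples:
            self._out.setdefault(t.subject, {}).setdefault(t.object, []).append(t)
            self._in.setdefault(t.object, set()).add(t.subject)
        self.relation_inventory: tuple[str, ...] = tuple(
            sorted({t.predicate for t in self.triples})
        )

    # -- adjacency ---------------------------------------------------------
    def out_neighbours(self, cid: str) -> set[str]:
        return set(self._out.get(cid, ()))

    def in_neighbours(self, cid: str) -> set[str]:
        return set(self._in.get(cid, ()))

    def outdegree(self, cid: str) -> int:
        """Number of distinct out-neighbours (graph degree, not row count)."""
        return len(self._out.get(cid, ()))

    def edge_triples(self, subject: str, obj: str) -> list[RelationTriple]:
        return list(self._out.get(subject, {}).get(obj, ()))

    def has_pair(self, subject: str, obj: str) -> bool:
        return obj in self._out.get(subject, {})

    # -- derived inventories ----------------------------------------------
    @property
    def n_triples(self) -> int:
        return len(self.triples)

    def semtype_inventory(self) -> SemanticTypeInventory:
        return SemanticTypeInventory(
            t for c in self.concepts.values() for t in c.semtypes
        )

    def semtype_map(self) -> dict[str, frozenset[str]]:
        return {cid: c.semtypes for cid, c in self.concepts.items()}

    def replace_triples(self, triples: Sequence[RelationTriple]) -> "KnowledgeSnapshot":
        """New snapshot with the given triples; concepts pruned to endpoints."""
        keep = {t.subject for t in triples} | {t.object for t in triples}
        return KnowledgeSnapshot(
            self.date_label,
            {cid: c for cid, c in self.concepts.items() if cid in keep},
            triples,
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, KnowledgeSnapshot)
            and self.date_label == other.date_label
            and self.triples == other.triples
            and self.concepts == other.concepts
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RRFDialect:
    """Column map for the pipe-delimited relation / semantic-type format.

    ``count_col`` is optional: when present the column carries an integer
    occurrence count, otherwise each row contributes one occurrence.
    """

    subject_col: int = 0
    relation_col: int = 1
    object_col: int = 2
    count_col: int | None = None
    delimiter: str = "|"


def _read_delimited(path: Path, dialect: RRFDialect, n_fields: int):
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    rows, bad = [], 0
    needed = [dialect.subject_col, dialect.relation_col, dialect.object_col][:n_fields]
    if dialect.count_col is not None:
        needed = needed + [dialect.count_col]
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(dialect.delimiter)
            if max(needed) >= len(parts) or any(not parts[i] for i in needed):
                bad += 1
                continue
            rows.append(parts)
    total = len(rows) + bad
    if bad:
        log.warning("%s: skipped %d malformed of %d lines", path, bad, total)
    if total and bad / total > 0.5:
        raise DataError(
            f"{path}: {bad}/{total} lines malformed; wrong dialect or delimiter?"
        )
    return rows, bad


def read_rrf_relations(
    path: str | Path,
    dialect: RRFDialect = RRFDialect(),
    negative_prefix: str = "NEG",
) -> list[RelationTriple]:
    """Parse pipe-delimited relation rows into aggregated triples.

    Duplicate (subject, predicate, object) rows have their counts summed.
    Malformed lines are skipped with a logged tally; a majority of malformed
    lines is treated as a dialect error and raised.
    """
    rows, _ = _read_delimited(Path(path), dialect, 3)
    triples = []
    for parts in rows:
        count = 1
        if dialect.count_col is not None:
            try:
                count = int(parts[dialect.count_col])
            except ValueError:
                continue
        pred = parts[dialect.relation_col]
        triples.append(
            RelationTriple(
                subject=parts[dialect.subject_col],
                predicate=pred,
                object=parts[dialect.object_col],
                count=count,
                negated=pred.startswith(negative_prefix),
            )
        )
    return aggregate_triples(triples)


def read_predications(
    path: str | Path, negative_prefix: str = "NEG"
) -> list[RelationTriple]:
    """Parse a predication table (header with subject_cui/predicate/object_cui).

    The delimiter (tab or comma) is sniffed.  Predicates starting with
    ``negative_prefix`` are flagged ``negated`` for the filtering stage.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as exc:  # noqa: BLE001 - surface as a data error
        raise DataError(f"{path}: could not parse predication table: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("subject_cui", "predicate", "object_cui") if c not in cols]
    if missing:
        raise DataError(f"{path}: predication table lacks columns {missing}")
    df = df.dropna(subset=[cols["subject_cui"], cols["predicate"], cols["object_cui"]])
    triples = [
        RelationTriple(
            subject=s,
            predicate=p,
            object=o,
            negated=p.startswith(negative_prefix),
        )
        for s, p, o in zip(
            df[cols["subject_cui"]], df[cols["predicate"]], df[cols["object_cui"]]
        )
    ]
    return aggregate_triples(triples)


def read_semtypes(
    path: str | Path,
    concept_col: int = 0,
    type_col: int = 1,
    delimiter: str = "|",
) -> dict[str, frozenset[str]]:
    """Parse pipe-delimited (concept id, semantic type) rows into a mapping."""
    dialect = RRFDialect(
        subject_col=concept_col, relation_col=type_col, object_col=type_col,
        delimiter=delimiter,
    )
    rows, _ = _read_delimited(Path(path), dialect, 2)
    mapping: dict[str, set[str]] = {}
    for parts in rows:
        mapping.setdefault(parts[concept_col], set()).add(parts[type_col])
    return {cid: frozenset(ts) for cid, ts in mapping.items()}


def write_rrf_relations(
    triples: Iterable[RelationTriple],
    path: str | Path,
    dialect: RRFDialect = RRFDialect(count_col=3),
) -> None:
    """Write triples in the pipe-delimited dialect, rows sorted
    (subject, predicate, object) so output is byte-stable.

    Without a ``count_col`` in the dialect, a triple of count *k* is written
    as *k* identical rows (multiset semantics); with one, counts are written
    in that column.
    """
    triples = aggregate_triples(triples)
    with open(path, "w") as fh:
        for t in triples:
            if dialect.count_col is not None:
                fields = ["", "", "", ""]
                fields[dialect.count_col] = str(t.count)
                reps = 1
            else:
                fields = ["", "", ""]
                reps = t.count
            fields[dialect.subject_col] = t.subject
            fields[dialect.relation_col] = t.predicate
            fields[dialect.object_col] = t.object
            line = dialect.delimiter.join(fields) + "\n"
            fh.write(line * reps)


def write_semtypes(
    semtypes: Mapping[str, Iterable[str]], path: str | Path, delimiter: str = "|"
) -> None:
    with open(path, "w") as fh:
        for cid in sorted(semtypes):
            for st in sorted(semtypes[cid]):
                fh.write(f"{cid}{delimiter}{st}\n")


# ---------------------------------------------------------------------------
# ISA merging
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        # keep the lexicographically smallest id as the class root so the
        # representative is input-order independent
        lo, hi = sorted((ra, rb))
        self.parent[hi] = lo


def merge_isa_classes(
    triples: Iterable[RelationTriple], isa_label: str = "isa"
) -> tuple[list[RelationTriple], dict[str, str]]:
    """Collapse ISA-connected concepts into equivalence classes.

    ISA edges are treated as undirected for grouping; every concept in a
    class is rewritten onto the lexicographically smallest member.  ISA
    triples themselves and any self-loops produced by the rewrite are
    dropped; duplicate rewritten triples aggregate their counts.

    Returns the rewritten triples and a mapping from every concept id seen
    in the input to its class representative (identity for unmerged ids).
    """
    triples = list(triples)
    uf = _UnionFind()
    ids: set[str] = set()
    for t in triples:
        ids.update((t.subject, t.object))
        if t.predicate == isa_label:
            uf.union(t.subject, t.object)
    mapping = {cid: uf.find(cid) for cid in ids}
    rewritten = [
        replace(t, subject=mapping[t.subject], object=mapping[t.object])
        for t in triples
        if t.predicate != isa_label
    ]
    rewritten = [t for t in rewritten if t.subject != t.object]
    return aggregate_triples(rewritten), mapping


def merge_semtype_map(
    semtypes: Mapping[str, Iterable[str]], mapping: Mapping[str, str]
) -> dict[str, frozenset[str]]:
    """Re-key a semantic-type mapping onto class representatives.

    A merged class carries the union of its members' types, preserving all
    typing evidence for the feature stage.
    """
    merged: dict[str, set[str]] = {}
    for cid, types in semtypes.items():
        rep = mapping.get(cid, cid)
        merged.setdefault(rep, set()).update(types)
    return {cid: frozenset(ts) for cid, ts in merged.items()}


def build_snapshot(
    triples: Sequence[RelationTriple],
    semtypes: Mapping[str, Iterable[str]],
    date_label: str,
) -> KnowledgeSnapshot:
    """Assemble a validated snapshot from parsed triples and type assignments.

    Triples with an endpoint that has no semantic-type assignment are dropped
    (such concepts cannot occupy any feature slot); the drop count is logged.
    An empty surviving triple set is fatal.
    """
    typed = {cid for cid, ts in semtypes.items() if ts}
    kept = [t for t in triples if t.subject in typed and t.object in typed]
    dropped = len(list(triples)) - len(kept)
    if dropped:
        log.warning(
            "%s: dropped %d triples with untyped endpoints", date_label, dropped
        )
    if not kept:
        raise DataError(f"snapshot {date_label!r} has no valid triples")
    concepts = {}
    for t in kept:
        for cid in (t.subject, t.object):
            if cid not in concepts:
                concepts[cid] = Concept(id=cid, semtypes=frozenset(semtypes[cid]))
    return KnowledgeSnapshot(date_label, concepts, aggregate_triples(kept))
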