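"""Open-discovery A-B-C closure.

For a source concept A, every B with a stored triple A->B is pursued, and
every C with a stored triple B->C is proposed as hidden knowledge (A, C)
provided no direct triple A->C exists and A != C.  Relation labels on the
two legs are carried along as witnesses but the closure itself ignores
them: whether A *treats* B or merely *coexists with* B, the path counts.

Pairs are ordered (the stored triple direction is followed); candidate
enumeration order is lexicographic by (A, C) so output files and any
downstream sampling are reproducible.  Stoplisted concepts are barred from
the B role only -- they may still appear as A or C.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import AbstractSet, Iterable, Iterator

from .errors import DataError
from .kg import KnowledgeSnapshot

__all__ = [
    "LinkWitness",
    "CandidatePair",
    "known_pairs",
    "abc_closure",
    "iter_abc_closure",
    "linking_term_counts",
    "write_candidates",
    "read_candidates",
]


@dataclass(frozen=True, order=True)
class LinkWitness:
    """One A->B->C path instance: the linking term and both leg predicates."""

    b: str
    rel_ab: str
    rel_bc: str


@dataclass(frozen=True)
class CandidatePair:
    """A proposed hidden pair (A, C) with all its linking-term witnesses."""

    source: str
    target: str
    links: tuple[LinkWitness, ...]

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)

    @property
    def linking_terms(self) -> frozenset[str]:
        return frozenset(w.b for w in self.links)

    @property
    def n_linking_terms(self) -> int:
        return len(self.linking_terms)

    def __post_init__(self) -> None:
        if not self.links:
            raise DataError(f"candidate {self.pair} has no link witnesses")
        if self.source == self.target:
            raise DataError(f"candidate {self.pair} is a self-pair")


def known_pairs(snapshot: KnowledgeSnapshot) -> set[tuple[str, str]]:
    """All ordered (subject, object) pairs asserted by at least one triple."""
    return {(t.subject, t.object) for t in snapshot.triples}


def iter_abc_closure(
    snapshot: KnowledgeSnapshot, stoplist: AbstractSet[str] = frozenset()
) -> Iterator[CandidatePair]:
    """Stream candidate pairs in lexicographic (A, C) order.

    Memory is proportional to one source concept's reachable set at a time,
    which keeps full-vocabulary runs feasible where the dense pair matrix
    would not be.
    """
    if snapshot.n_triples == 0:
        raise DataError("cannot run discovery on an empty snapshot")
    for a in sorted(snapshot.concepts):
        reach: dict[str, list[LinkWitness]] = {}
        for b in snapshot.out_neighbours(a):
            if b in stoplist:
                continue
            ab_rels = [t.predicate for t in snapshot.edge_triples(a, b)]
            for c in snapshot.out_neighbours(b):
                if c == a or snapshot.has_pair(a, c):
                    continue
                witnesses = reach.setdefault(c, [])
                for t_bc in snapshot.edge_triples(b, c):
                    for r_ab in ab_rels:
                        witnesses.append(LinkWitness(b, r_ab, t_bc.predicate))
        for c in sorted(reach):
            yield CandidatePair(source=a, target=c, links=tuple(sorted(reach[c])))


def abc_closure(
    snapshot: KnowledgeSnapshot, stoplist: AbstractSet[str] = frozenset()
) -> list[CandidatePair]:
    """Materialized closure, sorted by (source, target)."""
    return list(iter_abc_closure(snapshot, stoplist))


def linking_term_counts(
    snapshot: KnowledgeSnapshot, stoplist: AbstractSet[str] = frozenset()
) -> Counter:
    """Number of distinct candidate (A, C) pairs each concept links.

    This is the counting unit behind the automatic stoplist: a term's
    linking occurrences only exist relative to proposed pairs, so the count
    is over pairs witnessed, not over raw triples.
    """
    counts: Counter = Counter()
    for pair in iter_abc_closure(snapshot, stoplist):
        counts.update(pair.linking_terms)
    return counts


# ---------------------------------------------------------------------------
# TSV persistence
# ---------------------------------------------------------------------------

_HEADER = "source\ttarget\tn_linking_terms\tlinks\n"


def write_candidates(pairs: Iterable[CandidatePair], path: str | Path) -> None:
    """Write candidates as TSV: source, target, n, 'B:rel_AB:rel_BC;...'."""
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for p in pairs:
            links = ";".join(f"{w.b}:{w.rel_ab}:{w.rel_bc}" for w in p.links)
            fh.write(f"{p.source}\t{p.target}\t{p.n_linking_terms}\t{links}\n")


def read_candidates(path: str | Path) -> list[CandidatePair]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"candidate file not found: {path}")
    pairs = []
    with open(path) as fh:
        header = fh.readline()
        if header != _HEADER:
            raise DataError(f"{path}: unrecognized candidate TSV header")
        for line in fh:
            src, tgt, _n, links = line.rstrip("\n").split("\t")
            witnesses = tuple(
                LinkWitness(*w.split(":")) for w in links.split(";") if w
            )
            pairs.append(CandidatePair(source=src, target=tgt, links=witnesses))
    return pairs
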