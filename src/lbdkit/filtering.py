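"""Triple-level and term-level filters applied before discovery.

Three filter families are supported, mirroring the knowledge-cleaning
steps a large-scale discovery run needs: (1) a minimum relation frequency
(infrequent, often disused relations are dropped), (2) a relation
blacklist plus removal of negated predications (``NEG_*``), and (3)
removal of promiscuous terms -- concepts whose outdegree exceeds a cap,
and an automatically built stoplist of common linking terms.

Boundary semantics are literal: "minimum frequency f" keeps count >= f,
while the outdegree cap and linking-term cap are strict ("exceeding" /
"more than").  The canonical order is min-frequency -> blacklist ->
outdegree -> stoplist, running the cheap per-triple filters before the
closure-based stoplist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import AbstractSet, Iterable, Mapping

import yaml

from . import discovery
from .kg import KnowledgeSnapshot

log = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "apply_min_frequency",
    "apply_relation_blacklist",
    "apply_outdegree_filter",
    "build_linking_stoplist",
    "apply_semtype_restriction",
    "apply_filters",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and switches for the filtering stage.

    Defaults are the full-vocabulary operating point: relation frequency
    >= 10, outdegree cap 5000, linking-term cap 10,000, negated
    predications dropped.  The optional semantic-type restriction (keep
    only candidates whose source/target types intersect given sets) is off
    by default because it shrinks gold standards drastically.
    """

    min_rel_freq: int = 10
    outdegree_max: int = 5000
    lt_freq_max: int = 10_000
    relation_blacklist: frozenset[str] = frozenset()
    drop_negative: bool = True
    semtype_restriction: tuple[frozenset[str], frozenset[str]] | None = None

    def __post_init__(self) -> None:
        for name in ("min_rel_freq", "outdegree_max", "lt_freq_max"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    def to_dict(self) -> dict:
        d = {
            "min_rel_freq": self.min_rel_freq,
            "outdegree_max": self.outdegree_max,
            "lt_freq_max": self.lt_freq_max,
            "relation_blacklist": sorted(self.relation_blacklist),
            "drop_negative": self.drop_negative,
        }
        if self.semtype_restriction is not None:
            d["semtype_restriction"] = {
                "source_types": sorted(self.semtype_restriction[0]),
                "target_types": sorted(self.semtype_restriction[1]),
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterConfig":
        d = dict(d)
        restr = d.pop("semtype_restriction", None)
        if restr is not None:
            restr = (
                frozenset(restr["source_types"]),
                frozenset(restr["target_types"]),
            )
        return cls(
            min_rel_freq=d.get("min_rel_freq", 10),
            outdegree_max=d.get("outdegree_max", 5000),
            lt_freq_max=d.get("lt_freq_max", 10_000),
            relation_blacklist=frozenset(d.get("relation_blacklist", ())),
            drop_negative=d.get("drop_negative", True),
            semtype_restriction=restr,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def apply_min_frequency(
    snapshot: KnowledgeSnapshot, min_rel_freq: int
) -> KnowledgeSnapshot:
    """Drop triples asserted fewer than ``min_rel_freq`` times (inclusive keep)."""
    if min_rel_freq == 0:
        return snapshot
    kept = [t for t in snapshot.triples if t.count >= min_rel_freq]
    return snapshot.replace_triples(kept)


def apply_relation_blacklist(
    snapshot: KnowledgeSnapshot,
    blacklist: AbstractSet[str] = frozenset(),
    drop_negative: bool = True,
) -> KnowledgeSnapshot:
    """Drop triples whose predicate is blacklisted or flagged negated."""
    unknown = set(blacklist) - set(snapshot.relation_inventory)
    if unknown:
        log.warning(
            "blacklist entries absent from relation inventory: %s", sorted(unknown)
        )
    kept = [
        t
        for t in snapshot.triples
        if t.predicate not in blacklist and not (drop_negative and t.negated)
    ]
    return snapshot.replace_triples(kept)


def apply_outdegree_filter(
    snapshot: KnowledgeSnapshot, outdegree_max: int
) -> KnowledgeSnapshot:
    """Remove concepts whose outdegree strictly exceeds the cap.

    Outdegree counts distinct out-neighbours.  Removal takes all incident
    triples with it and is applied once -- degrees are not re-examined
    after removal, so there is no cascade.
    """
    hubs = {
        cid for cid in snapshot.concepts if snapshot.outdegree(cid) > outdegree_max
    }
    if not hubs:
        return snapshot
    log.info("outdegree filter removed %d concepts", len(hubs))
    kept = [
        t for t in snapshot.triples if t.subject not in hubs and t.object not in hubs
    ]
    return snapshot.replace_triples(kept)


def build_linking_stoplist(
    snapshot: KnowledgeSnapshot, lt_freq_max: int
) -> set[str]:
    """Automatic stoplist of common linking terms.

    A first-pass closure is run with no stoplist; every concept that acts
    as a linking term for strictly more than ``lt_freq_max`` distinct
    candidate pairs is stoplisted.  Callers then re-run the closure with
    the returned set excluded from the B role.
    """
    if snapshot.n_triples == 0:
        return set()
    counts = discovery.linking_term_counts(snapshot)
    stop = {b for b, n in counts.items() if n > lt_freq_max}
    if stop:
        log.info("stoplisted %d common linking terms", len(stop))
    return stop


def apply_semtype_restriction(
    pairs: Iterable[discovery.CandidatePair],
    restriction: tuple[AbstractSet[str], AbstractSet[str]],
    semtypes: Mapping[str, AbstractSet[str]],
) -> list[discovery.CandidatePair]:
    """Keep candidates whose source/target types intersect the given sets.

    Follows the source-type / target-type restriction strategy (e.g.
    diseases as sources, chemicals & drugs as targets); off by default in
    :class:`FilterConfig`.
    """
    src_types, tgt_types = (set(restriction[0]), set(restriction[1]))
    return [
        p
        for p in pairs
        if semtypes.get(p.source, frozenset()) & src_types
        and semtypes.get(p.target, frozenset()) & tgt_types
    ]


def apply_filters(
    snapshot: KnowledgeSnapshot, config: FilterConfig
) -> tuple[KnowledgeSnapshot, set[str]]:
    """Run the per-triple filters in canonical order and build the stoplist.

    Returns the filtered snapshot and the linking-term stoplist to pass to
    the closure.  The stoplist excludes terms from the B role only, so it
    is returned rather than baked into the snapshot.
    """
    snap = apply_min_frequency(snapshot, config.min_rel_freq)
    snap = apply_relation_blacklist(
        snap, config.relation_blacklist, config.drop_negative
    )
    snap = apply_outdegree_filter(snap, config.outdegree_max)
    stoplist = build_linking_stoplist(snap, config.lt_freq_max)
    return snap, stoplist
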