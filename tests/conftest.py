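"""Shared fixtures: tiny hand-built snapshots and the session-wide
synthetic three-date corpus with its derived pipeline artifacts."""

from __future__ import annotations

from dataclasses import dataclass, replace

import pytest

from lbdkit import anomaly, discovery, features, filtering, kg, synthetic


def make_snapshot(edges, semtypes=None, date="date1", counts=None):
    """Snapshot from a list of (subject, predicate, object) tuples.

    Concepts default to a single shared semantic type unless ``semtypes``
    provides one; ``counts`` optionally maps (s, p, o) -> count.
    """
    counts = counts or {}
    triples = [
        kg.RelationTriple(
            subject=s, predicate=p, object=o, count=counts.get((s, p, o), 1),
            negated=p.startswith("NEG"),
        )
        for s, p, o in edges
    ]
    ids = {t.subject for t in triples} | {t.object for t in triples}
    st = {cid: frozenset({"type_a"}) for cid in ids}
    if semtypes:
        st.update({k: frozenset(v) for k, v in semtypes.items()})
    return kg.build_snapshot(triples, st, date)


@pytest.fixture(scope="session")
def fixture7() -> synthetic.SyntheticFixture:
    """The default synthetic corpus (reference study conditions, seed 7)."""
    return synthetic.generate_fixture()


@dataclass
class PipelineArtifacts:
    """Filtered snapshots, closures and feature matrices for fixture7."""

    fixture: synthetic.SyntheticFixture
    snap1: kg.KnowledgeSnapshot
    snap2: kg.KnowledgeSnapshot
    snap3: kg.KnowledgeSnapshot
    stop1: set
    stop2: set
    hk1: list
    hk2: list
    layout: features.FeatureLayout
    pr1: features.PageRankWeights
    pr2: features.PageRankWeights
    X1: object
    X2: object


@pytest.fixture(scope="session")
def artifacts(fixture7) -> PipelineArtifacts:
    s1, s2, s3 = fixture7.snapshots()
    f1, stop1 = filtering.apply_filters(s1, fixture7.filters)
    f2, stop2 = filtering.apply_filters(s2, fixture7.filters)
    f3, _ = filtering.apply_filters(s3, fixture7.filters)
    hk1 = discovery.abc_closure(f1, stop1)
    hk2 = discovery.abc_closure(f2, stop2)
    layout = features.build_layout(f2, f1)
    pr1 = features.compute_pagerank(f1)
    pr2 = features.compute_pagerank(f2)
    X1 = features.featurize_batch(hk1, layout, pr1, f1.semtype_map())
    X2 = features.featurize_batch(hk2, layout, pr2, f2.semtype_map())
    return PipelineArtifacts(
        fixture=fixture7, snap1=f1, snap2=f2, snap3=f3, stop1=stop1,
        stop2=stop2, hk1=hk1, hk2=hk2, layout=layout, pr1=pr1, pr2=pr2,
        X1=X1, X2=X2,
    )


@pytest.fixture(scope="session")
def tiny_spec() -> synthetic.SyntheticSpec:
    """A miniature generator spec for fast CLI / IO tests."""
    return replace(
        synthetic.SyntheticSpec(),
        n_concepts=300,
        mean_outdegree=3.0,
        hub_count=1,
        hub_outdegree=60,
        stop_term_fanin=25,
        stop_term_fanout=25,
        n_isa_pairs=8,
        n_specialist_concepts=20,
        n_planted_interesting=0,
        growth_rate=0.03,
        outdegree_max=40,
        lt_freq_max=300,
        seed=11,
    )
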