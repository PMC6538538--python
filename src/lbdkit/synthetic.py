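"""Synthetic three-date knowledge fixtures with planted ground truth.

The generator emulates the statistical structure the discovery pipeline
assumes in a real thesaurus-scale corpus, at desk scale:

* a concept inventory where each concept carries 1-3 semantic types drawn
  from a skewed (Zipf-like) type distribution, so some type combinations
  are common and some rare;
* directed relation triples with labels and occurrence counts, including
  a fraction of negated predicates and a small ISA forest to exercise
  class merging;
* a few promiscuous hub concepts whose outdegree exceeds the (fixture-
  scaled) cap, and one common linking term that connects more candidate
  pairs than the stoplist threshold allows;
* snapshot growth over three dates in which new direct pairs are
  confirmations of earlier closure candidates -- background confirmations
  are biased toward candidates with MANY linking terms (trivial knowledge
  tends to be multiply connected), while a small planted subpopulation of
  "interesting" links has the opposite signature: few linking terms and a
  rare source/target semantic-type combination.

Every random choice flows from one seed, and the ground-truth record
(planted pairs, confirmations per window, hub ids, linking-term counts,
per-relation counts) is what the test suite checks pipeline output
against.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import discovery, features, filtering, kg
from .errors import DataError

log = logging.getLogger(__name__)

__all__ = ["SyntheticSpec", "SyntheticFixture", "generate_fixture",
           "write_fixture_files", "read_fixture_files", "RELATION_POOL"]

RELATION_POOL = [
    "affects", "associated_with", "causes", "coexists_with", "complicates",
    "disrupts", "has_ingredient", "interacts_with", "manifestation_of",
    "may_prevent", "may_treat", "precedes", "predisposes", "prevents",
    "treats", "stimulates", "produces", "augments",
]

DATE_LABELS = ("date1", "date2", "date3")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; the defaults are the reference study conditions.

    ``mean_outdegree`` controls base edge density (edges ~= n_concepts *
    mean_outdegree); ``growth_rate`` is the fraction of the previous
    snapshot's triples added as new confirmations per date step.  Hub and
    stop-term fan parameters are sized to exceed the fixture-scaled filter
    thresholds recorded in :attr:`SyntheticFixture.filters`.
    """

    n_concepts: int = 2000
    n_semtypes: int = 20
    semtypes_per_concept: tuple[int, int] = (1, 3)
    n_relation_labels: int = 15
    mean_outdegree: float = 4.0
    growth_rate: float = 0.04
    n_planted_interesting: int = 25
    hub_count: int = 3
    hub_outdegree: int = 200
    stop_term_fanin: int = 80
    stop_term_fanout: int = 80
    negative_relation_fraction: float = 0.05
    n_isa_pairs: int = 30
    planted_lt_percentile: float = 10.0
    planted_combo_max_frac: float = 0.01
    n_specialist_concepts: int = 40
    specialist_mean_outdegree: float = 3.0
    n_rare_semtypes: int = 8
    n_rare_relations: int = 5
    seed: int = 7

    # filter thresholds scaled to the fixture (the full-vocabulary defaults
    # of 5000 / 10,000 would never trigger on a 2,000-concept graph)
    min_rel_freq: int = 2
    outdegree_max: int = 150
    lt_freq_max: int = 3000
    blacklisted_relation: str = "has_ingredient"

    def filter_config(self) -> filtering.FilterConfig:
        return filtering.FilterConfig(
            min_rel_freq=self.min_rel_freq,
            outdegree_max=self.outdegree_max,
            lt_freq_max=self.lt_freq_max,
            relation_blacklist=frozenset({self.blacklisted_relation}),
            drop_negative=True,
        )


@dataclass
class SyntheticFixture:
    """Raw triples per date plus everything needed to verify a pipeline run."""

    spec: SyntheticSpec
    triples_by_date: dict[str, list[kg.RelationTriple]]
    semtypes: dict[str, frozenset[str]]
    ground_truth: dict
    filters: filtering.FilterConfig

    def snapshot(self, date_label: str) -> kg.KnowledgeSnapshot:
        """ISA-merged, validated snapshot for one date (pre-filtering)."""
        merged, mapping = kg.merge_isa_classes(self.triples_by_date[date_label])
        semtypes = kg.merge_semtype_map(self.semtypes, mapping)
        return kg.build_snapshot(merged, semtypes, date_label)

    def snapshots(self) -> tuple[kg.KnowledgeSnapshot, ...]:
        return tuple(self.snapshot(d) for d in DATE_LABELS)


def _draw_semtypes(
    rng, spec: SyntheticSpec, specialist_idx: set[int]
) -> dict[str, frozenset[str]]:
    type_ids = [f"st{i:03d}" for i in range(spec.n_semtypes)]
    # the type inventory splits into a broad common band, drawn with a
    # steep power-law skew (real thesaurus type frequencies span orders of
    # magnitude), and a niche band carried only by specialist concepts
    n_common = spec.n_semtypes - spec.n_rare_semtypes
    weights = 1.0 / (1.0 + np.arange(n_common)) ** 2
    probs = weights / weights.sum()
    rare_band = list(range(n_common, spec.n_semtypes))
    lo, hi = spec.semtypes_per_concept
    out = {}
    for i in range(spec.n_concepts):
        k = int(rng.integers(lo, hi + 1))
        if i in specialist_idx:
            chosen = rng.choice(rare_band, size=min(k, len(rare_band)),
                                replace=False)
        else:
            chosen = rng.choice(n_common, size=k, replace=False, p=probs)
        out[f"C{i:07d}"] = frozenset(type_ids[j] for j in sorted(chosen))
    return out


def _aggregate(raw: list[kg.RelationTriple]) -> list[kg.RelationTriple]:
    return kg.aggregate_triples(raw)


def _sample_pair_indices(rng, n: int, forbid_equal=True):
    a = int(rng.integers(n))
    b = int(rng.integers(n))
    while forbid_equal and b == a:
        b = int(rng.integers(n))
    return a, b


def generate_fixture(spec: SyntheticSpec = SyntheticSpec()) -> SyntheticFixture:
    """Build three nested snapshots and their ground truth.

    Growth between dates consists of confirmations of the previous date's
    closure candidates: date1->date2 confirmations (the future training
    outliers) are sampled with probability proportional to linking-term
    count, as are the date2->date3 background confirmations; the
    ``n_planted_interesting`` planted links are instead sampled from
    candidates with a linking-term count at or below the background 10th
    percentile AND a source/target semantic-type combination carried by
    fewer than 1% of candidates.  A feature-space separation margin for the
    planted set is computed and asserted before the fixture is returned,
    so a downstream recovery failure indicts the detector, not the data.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_concepts
    ids = [f"C{i:07d}" for i in range(n)]
    labels = RELATION_POOL[: spec.n_relation_labels]
    clean_labels = [
        r for r in labels if r != spec.blacklisted_relation
    ]
    # relation usage is skewed too: a handful of generic predicates carry
    # most assertions while the specific tail predicates are uncommon
    label_w = 1.0 / (1.0 + np.arange(len(labels))) ** 2
    label_p = label_w / label_w.sum()
    rare_labels = [
        r
        for r in labels[len(labels) - spec.n_rare_relations :]
        if r != spec.blacklisted_relation
    ]

    special = rng.choice(
        n, size=spec.hub_count + 1 + spec.n_specialist_concepts, replace=False
    )
    hub_idx = [int(i) for i in special[: spec.hub_count]]
    stop_idx = int(special[spec.hub_count])
    specialist_idx = [int(i) for i in special[spec.hub_count + 1 :]]
    special_set = set(hub_idx) | {stop_idx} | set(specialist_idx)
    semtypes = _draw_semtypes(rng, spec, set(specialist_idx))

    raw: list[kg.RelationTriple] = []

    def add(si: int, oi: int, pred: str, count: int, negated=False) -> None:
        raw.append(
            kg.RelationTriple(
                subject=ids[si], predicate=pred, object=ids[oi],
                count=count, negated=negated,
            )
        )

    # background graph over the mainstream (non-specialist) vocabulary
    mainstream = [i for i in range(n) if i not in set(specialist_idx)]
    m = int(round(n * spec.mean_outdegree))
    for _ in range(m):
        a, b = _sample_pair_indices(rng, len(mainstream))
        si, oi = mainstream[a], mainstream[b]
        pred = labels[int(rng.choice(len(labels), p=label_p))]
        negated = bool(rng.random() < spec.negative_relation_fraction)
        if negated:
            pred = "NEG_" + pred
        add(si, oi, pred, int(rng.integers(1, 20)), negated)

    # specialist niche: a sparse sub-graph of rare-typed concepts linked by
    # the uncommon tail predicates.  Interesting undiscovered links live in
    # such corners -- separately published specialist findings with little
    # generic connectivity -- and the planted pairs are later drawn from
    # the candidates this niche generates.
    n_spec_edges = int(round(spec.n_specialist_concepts
                             * spec.specialist_mean_outdegree))
    for _ in range(n_spec_edges):
        a, b = _sample_pair_indices(rng, len(specialist_idx))
        add(specialist_idx[a], specialist_idx[b],
            rare_labels[int(rng.integers(len(rare_labels)))],
            int(rng.integers(2, 20)))

    # promiscuous hubs: outdegree above the cap, edges that survive the
    # per-triple filters so the outdegree filter is what removes them
    for h in hub_idx:
        targets = rng.choice(len(mainstream), size=spec.hub_outdegree + 1,
                             replace=False)
        targets = [mainstream[int(t)] for t in targets
                   if mainstream[int(t)] != h][: spec.hub_outdegree]
        for t in targets:
            add(h, t, clean_labels[int(rng.integers(len(clean_labels)))],
                int(rng.integers(2, 20)))

    # one common linking term: large fan-in x fan-out, so its linking-pair
    # count exceeds the stoplist threshold while its outdegree stays legal
    fan_in = rng.choice(len(mainstream), size=spec.stop_term_fanin + 10,
                        replace=False)
    fan_in = [mainstream[int(t)] for t in fan_in
              if mainstream[int(t)] != stop_idx][: spec.stop_term_fanin]
    fan_out = rng.choice(len(mainstream), size=spec.stop_term_fanout + 10,
                         replace=False)
    fan_out = [mainstream[int(t)] for t in fan_out
               if mainstream[int(t)] != stop_idx][: spec.stop_term_fanout]
    for s in fan_in:
        add(s, stop_idx, clean_labels[int(rng.integers(len(clean_labels)))],
            int(rng.integers(2, 20)))
    for t in fan_out:
        add(stop_idx, t, clean_labels[int(rng.integers(len(clean_labels)))],
            int(rng.integers(2, 20)))

    # a small ISA forest among ordinary concepts
    isa_pairs = []
    ordinary = [i for i in range(n) if i not in special_set]
    chosen = rng.choice(len(ordinary), size=2 * spec.n_isa_pairs, replace=False)
    for j in range(spec.n_isa_pairs):
        child, parent = ordinary[int(chosen[2 * j])], ordinary[int(chosen[2 * j + 1])]
        add(child, parent, "isa", 10)
        isa_pairs.append((ids[child], ids[parent]))

    triples1 = _aggregate(raw)
    fcfg = spec.filter_config()

    def merged_snapshot(triples, label):
        merged, mapping = kg.merge_isa_classes(triples)
        return (
            kg.build_snapshot(merged, kg.merge_semtype_map(semtypes, mapping), label),
            mapping,
        )

    def closure_candidates(triples, label):
        snap, _ = merged_snapshot(triples, label)
        fsnap, stoplist = filtering.apply_filters(snap, fcfg)
        return fsnap, stoplist, discovery.abc_closure(fsnap, stoplist)

    def sample_confirmations(cands, k, exclude=frozenset()):
        pool = [c for c in cands if c.pair not in exclude]
        if k > len(pool):
            raise DataError(
                f"requested {k} confirmations but only {len(pool)} candidates"
            )
        w = np.array([c.n_linking_terms for c in pool], dtype=float)
        picked = rng.choice(len(pool), size=k, replace=False, p=w / w.sum())
        return [pool[int(i)] for i in picked]

    def confirmation_triples(chosen):
        out = []
        for c in chosen:
            pred = clean_labels[int(rng.integers(len(clean_labels)))]
            out.append(
                kg.RelationTriple(
                    subject=c.source, predicate=pred, object=c.target,
                    count=int(rng.integers(2, 20)),
                )
            )
        return out

    # date1 -> date2 growth
    fsnap1, stop1, cands1 = closure_candidates(triples1, "date1")
    n_bg2 = int(round(spec.growth_rate * len(triples1)))
    bg2 = sample_confirmations(cands1, n_bg2)
    triples2 = _aggregate(triples1 + confirmation_triples(bg2))

    # date2 -> date3 growth: background confirmations + planted anomalies
    fsnap2, stop2, cands2 = closure_candidates(triples2, "date2")
    planted = _pick_planted(rng, spec, fsnap2, cands2)
    planted_pairs = {c.pair for c in planted}
    n_bg3 = int(round(spec.growth_rate * len(triples2)))
    bg3 = sample_confirmations(cands2, n_bg3, exclude=planted_pairs)
    planted_triples = [
        kg.RelationTriple(subject=c.source, predicate="may_treat",
                          object=c.target, count=int(rng.integers(5, 20)))
        for c in planted
    ]
    triples3 = _aggregate(triples2 + confirmation_triples(bg3) + planted_triples)

    margin = (
        _signature_margin(fsnap2, cands2, planted_pairs)
        if planted
        else None
    )
    if margin is not None and margin <= 1.0:
        raise DataError(
            f"planted links are not separated from background "
            f"(margin {margin:.2f} <= 1); fixture spec infeasible"
        )

    lt_counts = discovery.linking_term_counts(fsnap1)
    ground_truth = {
        "planted_pairs": sorted([list(p) for p in planted_pairs]),
        "background_confirmations": {
            "date2": sorted([list(c.pair) for c in bg2]),
            "date3": sorted([list(c.pair) for c in bg3]),
        },
        "hub_ids": sorted(ids[h] for h in hub_idx),
        "stop_term": ids[stop_idx],
        "specialist_ids": sorted(ids[i] for i in specialist_idx),
        "isa_pairs": sorted([list(p) for p in isa_pairs]),
        "linking_term_counts_date1": {k: v for k, v in sorted(lt_counts.items())},
        "per_relation_counts": {
            d: _relation_histogram(t)
            for d, t in zip(DATE_LABELS, (triples1, triples2, triples3))
        },
        "n_triples": {
            d: len(t) for d, t in zip(DATE_LABELS, (triples1, triples2, triples3))
        },
        "signature_margin": margin,
        "seed": spec.seed,
    }
    return SyntheticFixture(
        spec=spec,
        triples_by_date={
            "date1": triples1, "date2": triples2, "date3": triples3
        },
        semtypes=semtypes,
        ground_truth=ground_truth,
        filters=fcfg,
    )


def _relation_histogram(triples) -> dict[str, int]:
    hist: dict[str, int] = {}
    for t in triples:
        hist[t.predicate] = hist.get(t.predicate, 0) + t.count
    return dict(sorted(hist.items()))


def _pick_planted(rng, spec, fsnap2, cands2):
    """Candidates with few linking terms and a rare type combination.

    "Rare combination" is enforced at two levels: the joint source/target
    type-set pattern must occur in fewer than ``planted_combo_max_frac`` of
    candidates, and both endpoints must each carry at least one semantic
    type that is itself rare (below the same fraction) among candidate
    sources resp. targets.  The second condition is what gives planted
    vectors individually unusual feature slots; combinations of common
    types are jointly rare but geometrically unremarkable.
    """
    if spec.n_planted_interesting == 0:
        return []
    semtypes = fsnap2.semtype_map()
    n_vals = np.array([c.n_linking_terms for c in cands2])
    lt_cut = np.percentile(n_vals, spec.planted_lt_percentile)
    combos: dict[tuple[frozenset, frozenset], int] = {}
    src_type_freq: dict[str, int] = {}
    tgt_type_freq: dict[str, int] = {}
    lt_type_freq: dict[str, int] = {}
    rel_freq: dict[str, int] = {}
    for c in cands2:
        key = (semtypes[c.source], semtypes[c.target])
        combos[key] = combos.get(key, 0) + 1
        for st in semtypes[c.source]:
            src_type_freq[st] = src_type_freq.get(st, 0) + 1
        for st in semtypes[c.target]:
            tgt_type_freq[st] = tgt_type_freq.get(st, 0) + 1
        for b in c.linking_terms:
            for st in semtypes[b]:
                lt_type_freq[st] = lt_type_freq.get(st, 0) + 1
        for r in {w.rel_ab for w in c.links} | {w.rel_bc for w in c.links}:
            rel_freq[r] = rel_freq.get(r, 0) + 1
    max_combo = spec.planted_combo_max_frac * len(cands2)

    def rare_path(c):
        return any(
            min(lt_type_freq[st] for st in semtypes[b]) < max_combo
            for b in c.linking_terms
        )

    def rarity(c):
        """Number of individually rare feature slots the candidate lights up."""
        score = sum(src_type_freq[st] < max_combo for st in semtypes[c.source])
        score += sum(tgt_type_freq[st] < max_combo for st in semtypes[c.target])
        score += max(
            sum(lt_type_freq[st] < max_combo for st in semtypes[b])
            for b in c.linking_terms
        )
        rels = {w.rel_ab for w in c.links} | {w.rel_bc for w in c.links}
        score += sum(rel_freq[r] < max_combo for r in rels)
        return score

    eligible = [
        c
        for c in cands2
        if c.n_linking_terms <= lt_cut
        and combos[(semtypes[c.source], semtypes[c.target])] < max_combo
        and min(src_type_freq[st] for st in semtypes[c.source]) < max_combo
        and min(tgt_type_freq[st] for st in semtypes[c.target]) < max_combo
        and rare_path(c)
    ]
    if len(eligible) < spec.n_planted_interesting:
        raise DataError(
            f"only {len(eligible)} candidates carry the anomalous signature "
            f"but {spec.n_planted_interesting} planted links were requested; "
            f"lower n_planted_interesting or loosen the signature bounds"
        )
    # plant the most anomalous of the eligible candidates (ties broken
    # randomly): "anomalous by construction" means the planted signature
    # should light up as many individually rare slots as the data allows
    jitter = rng.random(len(eligible))
    order = sorted(range(len(eligible)),
                   key=lambda i: (-rarity(eligible[i]), jitter[i]))
    return [eligible[i] for i in order[: spec.n_planted_interesting]]


def _signature_margin(fsnap2, cands2, planted_pairs) -> float:
    """Ratio of planted to background median z-distance from the centroid.

    Computed in the pipeline's own feature space so it certifies that the
    planted subpopulation is geometrically separated before any detector
    sees it; > 1 means planted points sit farther out than typical
    background points.
    """
    layout = features.build_layout(fsnap2)
    pr = features.compute_pagerank(fsnap2)
    X = features.featurize_batch(cands2, layout, pr, fsnap2.semtype_map())
    dense = np.asarray(X.todense())
    mu = dense.mean(axis=0)
    sd = dense.std(axis=0)
    z = np.abs(dense - mu) / np.where(sd > 0, sd, 1.0)
    dist = np.linalg.norm(z, axis=1)
    is_planted = np.array([c.pair in planted_pairs for c in cands2])
    return float(np.median(dist[is_planted]) / np.median(dist[~is_planted]))


# ---------------------------------------------------------------------------
# File round trip
# ---------------------------------------------------------------------------

_WRITE_DIALECT = kg.RRFDialect(count_col=3)


def write_fixture_files(fixture: SyntheticFixture, directory: str | Path) -> dict:
    """Write the fixture in the pipe-delimited dialect plus JSON ground truth.

    Returns the mapping of logical names to paths.  Files round-trip
    through the readers: re-reading reproduces the in-memory triples.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create fixture directory {directory}: {exc}")
    paths = {}
    for date, triples in fixture.triples_by_date.items():
        p = directory / f"relations_{date}.rrf"
        kg.write_rrf_relations(triples, p, _WRITE_DIALECT)
        paths[f"relations_{date}"] = p
    p = directory / "semtypes.rrf"
    kg.write_semtypes(fixture.semtypes, p)
    paths["semtypes"] = p
    p = directory / "ground_truth.json"
    with open(p, "w") as fh:
        json.dump(fixture.ground_truth, fh, indent=1, sort_keys=True)
    paths["ground_truth"] = p
    p = directory / "filters.yaml"
    fixture.filters.to_yaml(p)
    paths["filters"] = p
    p = directory / "spec.json"
    with open(p, "w") as fh:
        json.dump(dataclasses.asdict(fixture.spec), fh, indent=1, sort_keys=True)
    paths["spec"] = p
    return paths


def read_fixture_files(directory: str | Path) -> SyntheticFixture:
    directory = Path(directory)
    with open(directory / "spec.json") as fh:
        spec_d = json.load(fh)
    spec_d["semtypes_per_concept"] = tuple(spec_d["semtypes_per_concept"])
    spec = SyntheticSpec(**spec_d)
    triples_by_date = {
        d: kg.read_rrf_relations(directory / f"relations_{d}.rrf", _WRITE_DIALECT)
        for d in DATE_LABELS
    }
    semtypes = kg.read_semtypes(directory / "semtypes.rrf")
    with open(directory / "ground_truth.json") as fh:
        ground_truth = json.load(fh)
    return SyntheticFixture(
        spec=spec,
        triples_by_date=triples_by_date,
        semtypes=semtypes,
        ground_truth=ground_truth,
        filters=filtering.FilterConfig.from_yaml(directory / "filters.yaml"),
    )
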