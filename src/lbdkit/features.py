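"""Concept weighting by PageRank and semantic-type feature vectors.

Each candidate hidden pair (A, C) with linking terms B_1..B_n is encoded
as a fixed-width numeric array over four blocks laid out after a leading
scalar:

    [ n | A semantic types | C semantic types | LT semantic types | relations ]

* slot 0 is n, the number of distinct linking terms (hypothesized to be
  inversely related to how interesting a pair is);
* the A block holds A's PageRank in every semantic-type slot A carries
  (a single-typed concept contributes exactly one non-zero), the C block
  likewise for C;
* the LT block accumulates, for each distinct linking term B, B's PageRank
  into each of B's type slots;
* the relation block accumulates, for each path witness (B, rel_AB,
  rel_BC), B's PageRank into the slot of rel_AB and the slot of rel_BC.

PageRank is computed over the filtered concept graph, directed as stored,
with uniform teleport; its stationary weights stand in for term importance
so that a path through a high-traffic generic concept and a path through a
specific one are encoded differently even when their semantic types agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .discovery import CandidatePair
from .errors import DataError
from .kg import KnowledgeSnapshot, SemanticTypeInventory

log = logging.getLogger(__name__)

__all__ = [
    "PageRankWeights",
    "FeatureLayout",
    "compute_pagerank",
    "build_layout",
    "featurize_pair",
    "featurize_batch",
    "write_feature_matrix",
]


@dataclass
class PageRankWeights:
    """Stationary random-walk distribution over snapshot concepts."""

    weights: dict[str, float]
    damping: float
    tol: float
    iterations_run: int
    converged: bool

    def __getitem__(self, cid: str) -> float:
        return self.weights[cid]


def compute_pagerank(
    snapshot: KnowledgeSnapshot,
    damping: float = 0.85,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> PageRankWeights:
    """Power-iteration PageRank on the directed concept graph.

    Edges are the stored triples (unweighted, parallel predicates collapse
    to one edge); dangling mass is redistributed uniformly.  Iteration
    stops when the L1 change drops below ``tol``; hitting ``max_iter``
    first logs a warning but still returns the last iterate.
    """
    if not 0 < damping < 1:
        raise ValueError(f"damping must be in (0, 1), got {damping}")
    if snapshot.n_triples == 0:
        raise DataError("cannot compute PageRank on an empty snapshot")
    nodes = sorted(snapshot.concepts)
    idx = {c: i for i, c in enumerate(nodes)}
    n = len(nodes)
    edges = {(idx[t.subject], idx[t.object]) for t in snapshot.triples}
    rows, cols = zip(*edges)
    data = np.ones(len(edges))
    adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    outdeg = np.asarray(adj.sum(axis=1)).ravel()
    dangling = outdeg == 0
    with np.errstate(divide="ignore"):
        inv = np.where(dangling, 0.0, 1.0 / np.maximum(outdeg, 1))
    transition = sp.diags(inv) @ adj  # row-stochastic on non-dangling rows

    p = np.full(n, 1.0 / n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        spread = transition.T @ p + p[dangling].sum() / n
        new = damping * spread + (1.0 - damping) / n
        if np.abs(new - p).sum() < tol:
            p = new
            converged = True
            break
        p = new
    if not converged:
        log.warning("PageRank did not converge in %d iterations", max_iter)
    return PageRankWeights(
        weights=dict(zip(nodes, p.tolist())),
        damping=damping,
        tol=tol,
        iterations_run=it,
        converged=converged,
    )


class FeatureLayout:
    """Slot layout of the feature array; derivable from inventories alone."""

    def __init__(
        self,
        semtype_inventory: SemanticTypeInventory,
        relation_inventory: Sequence[str],
    ):
        if len(semtype_inventory) == 0 or len(relation_inventory) == 0:
            raise DataError("feature layout requires non-empty inventories")
        self.semtypes = semtype_inventory
        self.relations: tuple[str, ...] = tuple(sorted(set(relation_inventory)))
        self.rel_index = {r: i for i, r in enumerate(self.relations)}
        s = len(self.semtypes)
        self.a_offset = 1
        self.c_offset = 1 + s
        self.lt_offset = 1 + 2 * s
        self.rel_offset = 1 + 3 * s
        self.total_length = 1 + 3 * s + len(self.relations)

    # block views, used by tests and by decision-point naming
    def a_block(self, v: np.ndarray) -> np.ndarray:
        return v[..., self.a_offset : self.c_offset]

    def c_block(self, v: np.ndarray) -> np.ndarray:
        return v[..., self.c_offset : self.lt_offset]

    def lt_block(self, v: np.ndarray) -> np.ndarray:
        return v[..., self.lt_offset : self.rel_offset]

    def rel_block(self, v: np.ndarray) -> np.ndarray:
        return v[..., self.rel_offset : self.total_length]

    def slot_name(self, i: int) -> str:
        """Human-readable meaning of slot ``i`` (e.g. 'LT:finding')."""
        if i == 0:
            return "number of linking terms"
        if i < self.c_offset:
            return f"A:{self.semtypes.types[i - self.a_offset]}"
        if i < self.lt_offset:
            return f"C:{self.semtypes.types[i - self.c_offset]}"
        if i < self.rel_offset:
            return f"LT:{self.semtypes.types[i - self.lt_offset]}"
        if i < self.total_length:
            return f"relation:{self.relations[i - self.rel_offset]}"
        raise IndexError(i)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, FeatureLayout)
            and self.semtypes == other.semtypes
            and self.relations == other.relations
        )


def build_layout(
    snapshot: KnowledgeSnapshot, *extra: KnowledgeSnapshot
) -> FeatureLayout:
    """Layout from a snapshot's inventories (optionally unioned with others).

    Passing the training and scoring snapshots together guarantees one
    layout covers both; a model is only meaningful for inputs featurized
    under the layout it was trained with.
    """
    types = {t for s in (snapshot, *extra) for c in s.concepts.values() for t in c.semtypes}
    rels = {r for s in (snapshot, *extra) for r in s.relation_inventory}
    return FeatureLayout(SemanticTypeInventory(types), sorted(rels))


def _fill_row(
    pair: CandidatePair,
    layout: FeatureLayout,
    pagerank: PageRankWeights,
    semtypes: Mapping[str, frozenset[str]],
    row: dict[int, float],
) -> None:
    st_index = layout.semtypes.index
    try:
        row[0] = float(pair.n_linking_terms)
        for st in semtypes[pair.source]:
            row[layout.a_offset + st_index[st]] = pagerank[pair.source]
        for st in semtypes[pair.target]:
            row[layout.c_offset + st_index[st]] = pagerank[pair.target]
        for b in pair.linking_terms:
            for st in semtypes[b]:
                slot = layout.lt_offset + st_index[st]
                row[slot] = row.get(slot, 0.0) + pagerank[b]
        for w in pair.links:
            pr_b = pagerank[w.b]
            for rel in (w.rel_ab, w.rel_bc):
                slot = layout.rel_offset + layout.rel_index[rel]
                row[slot] = row.get(slot, 0.0) + pr_b
    except KeyError as exc:
        raise DataError(
            f"pair {pair.pair}: unknown concept, semantic type or predicate "
            f"{exc.args[0]!r} for this layout"
        ) from exc


def featurize_pair(
    pair: CandidatePair,
    layout: FeatureLayout,
    pagerank: PageRankWeights,
    semtypes: Mapping[str, frozenset[str]],
) -> np.ndarray:
    """Dense feature array for one candidate pair."""
    row: dict[int, float] = {}
    _fill_row(pair, layout, pagerank, semtypes, row)
    v = np.zeros(layout.total_length)
    v[list(row)] = list(row.values())
    return v


def featurize_batch(
    pairs: Sequence[CandidatePair],
    layout: FeatureLayout,
    pagerank: PageRankWeights,
    semtypes: Mapping[str, frozenset[str]],
) -> sp.csr_matrix:
    """Sparse feature matrix; row order matches the input pair order."""
    data: list[float] = []
    indices: list[int] = []
    indptr = [0]
    for pair in pairs:
        row: dict[int, float] = {}
        _fill_row(pair, layout, pagerank, semtypes, row)
        for col in sorted(row):
            indices.append(col)
            data.append(row[col])
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.asarray(data), np.asarray(indices, dtype=np.int64), np.asarray(indptr)),
        shape=(len(pairs), layout.total_length),
    )


def write_feature_matrix(
    matrix: sp.spmatrix, layout: FeatureLayout, path: str | Path
) -> None:
    """Persist features as text triplets (row, col, value) plus a layout
    sidecar mapping every column to its meaning."""
    path = Path(path)
    coo = matrix.tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        fh.write(f"# shape {matrix.shape[0]} {matrix.shape[1]}\n")
        for i in order:
            fh.write(f"{coo.row[i]}\t{coo.col[i]}\t{coo.data[i]:.17g}\n")
    with open(path.with_suffix(path.suffix + ".layout"), "w") as fh:
        for i in range(layout.total_length):
            fh.write(f"{i}\t{layout.slot_name(i)}\n")
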