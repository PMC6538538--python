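# Methods

## Problem setting

Literature-based discovery (LBD) proposes *hidden knowledge*: pairs of
biomedical concepts (A, C) that are never directly related in any source,
but are connected through one or more intermediate *linking terms* B — A
relates to B in one place, B to C in another. Run over a full
thesaurus-scale relation store, the open-discovery A-B-C closure proposes
millions of pairs, almost all of which are valid but uninteresting
(already common knowledge, or trivially inferable). `lbdkit` implements
the re-ranking view of this problem: interesting hidden knowledge is rare
and differently shaped in feature space, so it can be surfaced by anomaly
detection rather than by ever-heavier filtering.

## Pipeline

1. **Ingestion** (`kg`). Two triple dialects are read into one model:
   pipe-delimited thesaurus-style rows (configurable columns, optional
   count column) and headered predication tables
   (`subject_cui`/`predicate`/`object_cui`). Duplicate triples aggregate
   counts. Concepts with no semantic-type assignment are dropped — they
   could not occupy any feature slot. Concepts connected by `ISA` are
   merged into equivalence classes (undirected grouping; representative =
   lexicographically smallest member; class types = union of member
   types), because a link to a concept's hierarchical variant is not a
   discovery.

2. **Filtering** (`filtering`), in order: minimum relation frequency
   (count >= threshold, default 10); relation blacklist plus removal of
   negated predicates (`NEG_*`); removal of concepts whose outdegree
   (distinct out-neighbours) strictly exceeds a cap (default 5000); and an
   automatic stoplist of common linking terms — concepts that act as the
   B term for strictly more than a threshold number of candidate pairs
   (default 10,000) in a first-pass closure, then excluded from the B role
   in a second pass. Boundary semantics are literal: "minimum" is
   inclusive, "exceeding"/"more than" strict. An optional source/target
   semantic-type restriction on candidates exists but is off by default
   (it shrinks gold standards to unusable sizes).

3. **Discovery** (`discovery`). The closure streams per source concept:
   candidates are ordered pairs (A, C) with at least one stored path
   A→B→C, no stored A→C, A ≠ C, and B not stoplisted. Every
   (B, rel_AB, rel_BC) witness is retained; relation labels play no role
   in whether a pair is proposed.

4. **Features** (`features`). Concept importance is PageRank over the
   filtered, directed concept graph (unweighted edges as stored, uniform
   teleport, dangling mass redistributed uniformly; damping 0.85,
   L1 tolerance 1e-8, max 200 iterations — canonical defaults, recorded
   in provenance). Each candidate becomes a sparse vector

   `[ n | A-semtype block | C-semtype block | LT-semtype block | relation block ]`

   where n is the distinct linking-term count; A's PageRank is written
   into each of A's type slots (multi-typed concepts write their full
   PageRank into every slot — block sum = PR(A)·|types(A)|); likewise for
   C; each distinct B adds its PageRank into its type slots; and each
   witness adds PR(B) to both of its leg-relation slots (relation-block
   sum = 2·Σ_witnesses PR(B)). No standardization is applied: the
   PageRank magnitudes are the weighting signal.

5. **Anomaly detection** (`anomaly`). The isolation forest (100 trees,
   subsample 256, explicit seed) is trained unsupervised on all
   training-window candidates, with its contamination set to the observed
   fraction of candidates later confirmed. The one-class SVM (RBF kernel,
   nu = max(observed outlier fraction, 0.01), gamma = 'scale') is trained
   on the unconfirmed (normal) candidates only, matching its novelty
   framing. One-class fitting is guarded by a memory budget on the
   implied n² kernel matrix (default 8 GiB); exceeding it raises a
   resource error that the experiment driver catches and reports, since
   the forest path remains valid at scales where the SVM is not.
   Rankings sort most-anomalous-first with ties broken by pair id.

6. **Evaluation** (`evaluation`). Three ordered snapshot dates: models
   are trained on candidates from date 1 with outliers annotated from
   date 2; candidates generated from date 2 are scored; the gold standard
   is the ordered pairs present at date 3 but absent at date 2, computed
   after identical ISA merging and filtering of both snapshots (otherwise
   vocabulary churn floods the gold set). Date-2 candidates exclude
   everything known at date 2 by construction, so they cannot overlap the
   date-2-confirmed training outliers; the pipeline asserts this
   no-leakage property on every run. Metrics are precision, recall and
   balanced F1 over ordered pairs (F1 = 2·tp/(|HK|+|GS|)); differences
   across splits use a classical paired t-test on per-split F values.
   The one-sided upper tail is the default: recomputing from the
   published per-split F columns reproduces the reported significance
   levels only under the one-sided reading (≈0.0014 / 0.019 / 0.0089
   against reported 0.0015 / 0.018 / 0.0094; the two-sided values would
   be twice as large).

## Decision-point inspection

Isolation trees draw split features uniformly at random, so raw split
frequency near the root carries no information about the data. What marks
a feature as an anomaly *decision point* is that, when drawn, its split
strands a small minority of the node's samples close to the root.
`inspect_decision_points` therefore counts, at depth ≤ a cutoff (default
2), splits whose smaller child holds at most a minority fraction (default
10%) of the node's training samples, and names the slots via the layout
("number of linking terms", "LT:st014", "relation:may_treat", ...).

## Synthetic data: what it emulates and what it does not

The generator (`synthetic`) produces three nested dated snapshots with
the structural features the method assumes, at desk scale (defaults:
2,000 concepts, 20 semantic types, 15 relation labels, mean outdegree 4,
4% growth per date step, seed 7):

- **Skewed type and relation usage.** Semantic types split into a broad
  common band drawn with a steep power-law skew and a niche band carried
  only by a small specialist subpopulation; relation labels are likewise
  power-law skewed. Real thesaurus type and predicate frequencies span
  orders of magnitude.
- **A specialist niche.** 40 rare-typed concepts sparsely interlinked by
  the uncommon tail predicates, with little generic connectivity. This is
  where plausible undiscovered links live — separately published
  specialist findings — and it is what makes the planted signature
  *geometrically* anomalous: a combination of individually common types
  is jointly rare but indistinguishable to axis-aligned partitioning,
  whereas niche candidates light up individually rare feature slots.
- **Filter targets.** Three hub concepts whose outdegree exceeds the
  fixture-scaled cap (150), and one common linking term whose fan-in ×
  fan-out linking count exceeds the fixture-scaled stoplist threshold
  (3,000); a small ISA forest; ~5% negated predicates; one blacklisted
  ingredient-style relation. Fixture-scaled thresholds are used because
  the full-vocabulary defaults can never trigger on a 2,000-concept
  graph.
- **Growth as confirmation.** New direct pairs between dates are
  confirmations of the previous date's closure candidates, sampled with
  probability proportional to linking-term count (trivial knowledge is
  multiply connected). The planted interesting links are the opposite:
  candidates with a linking-term count at or below the background 10th
  percentile, a source/target type-set combination carried by <1% of
  candidates, and individually rare source, target and linking-term
  types; among the eligible, the most anomalous (most rare slots) are
  planted. They appear as direct triples only at date 3, and are
  guaranteed discoverable candidates at date 2.
- **A generation-time separation certificate.** The generator featurizes
  all date-2 candidates through the pipeline's own feature stage and
  asserts that the planted subpopulation's median per-feature z-distance
  from the background centroid exceeds the background median (the
  recorded `signature_margin`, ≈10 under the defaults). A downstream
  recovery failure therefore indicts the detector, not the data.

Not emulated: real citation/publication dynamics, text extraction noise,
vocabulary churn between releases, and the absolute scale of a full
thesaurus (millions of pairs). Passing the end-to-end test shows the
mechanism works when interesting links genuinely occupy rare corners of
feature space; it does not bound performance on real corpora, where the
separation is weaker and training confirmations are scarcer.

## Numerical and design choices

- Deterministic orderings everywhere: inventories sorted
  lexicographically, candidates emitted in (A, C) order, rankings
  tie-broken by pair id, fixture generation driven by one seed.
- PageRank convergence is declared on the L1 change of the iterate;
  non-convergence at max_iter logs a warning and returns the last
  iterate rather than failing.
- Degenerate inputs are explicit errors, never NaN: zero-variance
  one-class training data, zero-variance paired differences, empty gold
  standards, single-distinct-row forests, empty snapshots.
- The experiment builds one feature layout from the union of the training
  and scoring snapshots' inventories, since a model is meaningful only
  for vectors laid out as its training data was. With nested snapshots
  the union equals the later snapshot's inventories.
- Problem sizes in the test suite and the acceptance script are the
  fixture defaults above (~29,000 date-2 candidates); the recovery
  statistic averages five forest seeds at fixed data.

## Known limitations

- The closure is single-hop (one linking term); multi-hop chains and
  closed discovery (finding B terms for a suspected A-C pair) are out of
  scope.
- Only stored triple directions are followed; a relation recorded solely
  as B→A contributes no A→B path.
- The one-class SVM's selected set is threshold-based via nu; no score
  calibration to probabilities is attempted for either detector.
- The semantic-network (type-graph) reading of the PageRank edge set is
  not implemented; the concept-graph reading is the only one the
  pipeline's inputs always support.
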