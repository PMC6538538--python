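# lbdkit

Literature-based discovery (LBD) with anomaly-detection re-ranking.

Biomedical researchers cannot read everything, so inferable connections
between separately published findings go unnoticed — famously, fish oil's
effects on blood viscosity and platelet aggregation, and Raynaud
disease's dependence on the same, sat in disjoint literatures. The
Swanson *A-B-C* model proposes such hidden pairs automatically: if A
relates to B in one source and B to C in another, with no direct A-C
relation anywhere, (A, C) is candidate hidden knowledge. The catch is
volume — a full thesaurus release generates millions of candidates, and
nearly all are true-but-trivial.

`lbdkit` treats *interesting* hidden knowledge as an anomaly. Each
candidate pair (A, C) with linking terms B₁..Bₙ becomes a feature vector

```
[ n | A semantic types | C semantic types | LT semantic types | relations ]
```

where semantic-type and relation slots are filled with PageRank weights
of the participating concepts (computed over the filtered concept-relation
graph). An isolation forest (100 trees) and a one-class SVM rank
candidates by anomaly score, and the selected anomalous subset — a small
fraction of the original output — is what a human would verify.
Evaluation is by three-date timeslicing: train on candidates from a
date-1 snapshot with outliers annotated from date 2, score candidates
from date 2, and compare against the gold standard of pairs that are new
between dates 2 and 3, with precision/recall/F₁ = 2·tp/(|HK|+|GS|) and
paired t-tests across timeslice splits.

The package is aimed at text-/knowledge-mining researchers who have
dated triple stores in either a pipe-delimited thesaurus-style format or
a SemRep-style predication table, and want a reproducible
discover → featurize → rank → evaluate pipeline plus a synthetic
benchmark with planted ground truth.

## Worked example

Generate a synthetic three-date corpus (2,000 concepts, planted
interesting links, ground truth on disk) and run the full timeslice
experiment:

```bash
lbdkit generate --out fx
lbdkit experiment \
  --relations1 fx/relations_date1.rrf \
  --relations2 fx/relations_date2.rrf \
  --relations3 fx/relations_date3.rrf \
  --semtypes fx/semtypes.rrf \
  --filter-config fx/filters.yaml \
  --seed 1 --out run
```

The command prints the per-system results from `run/report.json`
(abridged; your numbers will match exactly for the same seed):

```
{
 "original":         {"f1": 0.0268, "hk_size": 29032, "gs_size": 395, ...},
 "isolation_forest": {"f1": 0.0456, "hk_size": 438,  "tp": 19, ...},
 "one_class_svm":    {"f1": 0.0248, "hk_size": 493,  "tp": 11, ...}
}
```

Reading: the unranked closure proposed 29,032 hidden pairs of which 395
were confirmed by date 3 (F₁ = 0.0268 — recall 1, precision tiny). The
isolation forest flagged 438 pairs as anomalous and raised F₁ to 0.0456
while shrinking the set to verify by a factor of ~66. The same stages are
available as library calls (`lbdkit.discovery.abc_closure`,
`lbdkit.features.featurize_batch`, `lbdkit.anomaly.fit_isolation_forest`,
`lbdkit.evaluation.run_timeslice_experiment`, ...) and as the
intermediate subcommands `discover`, `featurize`, `fit`, `rank`,
`evaluate`.

## Layout

```
src/lbdkit/
  kg.py          # triples, snapshots, readers/writers, ISA merging
  filtering.py   # frequency / blacklist / outdegree / stoplist filters
  discovery.py   # A-B-C open-discovery closure
  features.py    # PageRank + semantic-type feature vectors
  anomaly.py     # isolation forest, one-class SVM, decision points
  evaluation.py  # gold standards, F1, paired t-tests, experiment driver
  synthetic.py   # three-date fixture generator with planted ground truth
  cli.py         # `lbdkit` command-line entry points
```
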