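"""Three-date timeslice evaluation of hidden-knowledge generation.

Because proposed hidden knowledge is by definition not yet recorded, it is
scored against the future: pick three ordered cutoff dates, train the
detector on candidates generated from the date-1 snapshot (labelling as
outliers those later confirmed by date 2), generate candidates from the
date-2 snapshot, and evaluate the selected subset against the gold
standard of pairs that are present at date 3 but absent at date 2.
Candidates generated at date 2 exclude everything already known at date 2,
so they cannot overlap the training-confirmed outliers -- the no-leakage
property is asserted at run time.

Performance is summarized as precision / recall / balanced F1 over ordered
pairs, and differences across timeslice splits are tested with a paired
one-sided t-test on the per-split F values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import anomaly, discovery, features, filtering
from .errors import ConfigError, DataError, DegenerateInputError, ResourceLimitError
from .kg import KnowledgeSnapshot

log = logging.getLogger(__name__)

__all__ = [
    "GoldStandard",
    "EvaluationResult",
    "SignificanceResult",
    "build_gold_standard",
    "label_training_outliers",
    "f1_from_counts",
    "evaluate_f1",
    "paired_ttest",
    "run_timeslice_experiment",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class GoldStandard:
    """Ordered pairs newly present in the later snapshot."""

    pairs: frozenset[Pair]
    window: tuple[str, str]


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    hk_size: int
    gs_size: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SignificanceResult:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    tail: str  # 'one-sided' | 'two-sided'

    def to_dict(self) -> dict:
        return asdict(self)


def build_gold_standard(
    earlier: KnowledgeSnapshot, later: KnowledgeSnapshot
) -> GoldStandard:
    """Pairs asserted in the later snapshot but not the earlier one.

    Both snapshots must have been put through the same ISA merging and
    relation filtering; otherwise vocabulary churn between releases floods
    the gold set with bookkeeping artifacts.
    """
    if earlier.date_label == later.date_label:
        raise ConfigError("gold standard requires two distinct snapshot dates")
    new = discovery.known_pairs(later) - discovery.known_pairs(earlier)
    return GoldStandard(
        pairs=frozenset(new), window=(earlier.date_label, later.date_label)
    )


def label_training_outliers(
    hk_earlier: Sequence[discovery.CandidatePair],
    snapshot_later: KnowledgeSnapshot,
) -> tuple[list[discovery.CandidatePair], list[discovery.CandidatePair]]:
    """Split training candidates into (normals, outliers).

    A candidate proposed from the earlier snapshot counts as an outlier --
    an interesting proposal -- exactly when the later snapshot confirms it
    as a direct pair.  The partition is exhaustive and disjoint.
    """
    confirmed = discovery.known_pairs(snapshot_later)
    normals = [p for p in hk_earlier if p.pair not in confirmed]
    outliers = [p for p in hk_earlier if p.pair in confirmed]
    return normals, outliers


def f1_from_counts(n_predicted: int, n_gold: int, tp: int) -> float:
    """Balanced F1 from set sizes: F1 = 2*tp / (|predicted| + |gold|)."""
    denom = n_predicted + n_gold
    return 2.0 * tp / denom if denom else 0.0


def evaluate_f1(predicted: set[Pair], gold: GoldStandard) -> EvaluationResult:
    """Precision / recall / balanced F1 of a predicted pair set."""
    if not gold.pairs:
        raise DataError("empty gold standard; evaluation is meaningless")
    tp = len(predicted & gold.pairs)
    fp = len(predicted) - tp
    fn = len(gold.pairs) - tp
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(gold.pairs)
    f1 = (
        2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    )
    return EvaluationResult(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        hk_size=len(predicted),
        gs_size=len(gold.pairs),
    )


def paired_ttest(
    f_a: Sequence[float], f_b: Sequence[float], tail: str = "one-sided"
) -> SignificanceResult:
    """Classical paired t-test on the differences f_b - f_a.

    The one-sided (upper-tail) alternative -- system b beats system a --
    is the default; ``tail='two-sided'`` gives the symmetric test.
    """
    a = np.asarray(f_a, dtype=float)
    b = np.asarray(f_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("paired samples must be equal-length 1-D sequences")
    n = len(a)
    if n < 2:
        raise DataError("paired t-test needs at least two paired observations")
    d = b - a
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError(
            "paired differences have zero variance; t statistic undefined"
        )
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    if tail == "one-sided":
        p = float(stats.t.sf(t, df))
    elif tail == "two-sided":
        p = float(2 * stats.t.sf(abs(t), df))
    else:
        raise ConfigError(f"unknown tail {tail!r}")
    return SignificanceResult(
        t_statistic=float(t), degrees_of_freedom=df, p_value=p, tail=tail
    )


# ---------------------------------------------------------------------------
# End-to-end orchestration
# ---------------------------------------------------------------------------


def run_timeslice_experiment(
    snapshot1: KnowledgeSnapshot,
    snapshot2: KnowledgeSnapshot,
    snapshot3: KnowledgeSnapshot,
    filter_config: filtering.FilterConfig = filtering.FilterConfig(),
    forest_params: anomaly.ForestParams | None = None,
    ocsvm_params: anomaly.OneClassParams | None = None,
    seed: int = 0,
) -> dict:
    """Run one train/test/evaluate timeslice and report per-system F1.

    Stages: filter all three snapshots identically -> closure(date1) ->
    annotate training outliers from date2 -> featurize and fit both
    detectors -> closure(date2) -> score and select -> evaluate the
    unranked, forest-selected and one-class-selected sets against the
    (date2, date3) gold standard.  A one-class memory failure is caught
    and reported rather than propagated, since the forest path remains
    valid.  The returned report is JSON-serializable and reproducible
    given the same inputs and seed.
    """
    labels = [snapshot1.date_label, snapshot2.date_label, snapshot3.date_label]
    if len(set(labels)) != 3:
        raise ConfigError(f"three distinct snapshot dates required, got {labels}")

    snap1, stop1 = filtering.apply_filters(snapshot1, filter_config)
    snap2, stop2 = filtering.apply_filters(snapshot2, filter_config)
    snap3, _ = filtering.apply_filters(snapshot3, filter_config)

    hk1 = discovery.abc_closure(snap1, stop1)
    normals, outliers = label_training_outliers(hk1, snap2)
    outlier_fraction = len(outliers) / len(hk1) if hk1 else 0.0

    layout = features.build_layout(snap2, snap1)
    pr1 = features.compute_pagerank(snap1)
    pr2 = features.compute_pagerank(snap2)
    semtypes1 = snap1.semtype_map()
    semtypes2 = snap2.semtype_map()

    X_train_all = features.featurize_batch(hk1, layout, pr1, semtypes1)
    X_train_norm = features.featurize_batch(normals, layout, pr1, semtypes1)

    hk2 = discovery.abc_closure(snap2, stop2)
    if filter_config.semtype_restriction is not None:
        hk2 = filtering.apply_semtype_restriction(
            hk2, filter_config.semtype_restriction, semtypes2
        )
    hk2_pairs = {p.pair for p in hk2}

    # no-leakage assertions: date-2 candidates are unknown at date 2, hence
    # disjoint from the date-2-confirmed training outliers
    known2 = discovery.known_pairs(snap2)
    assert not hk2_pairs & known2, "closure leaked known pairs"
    outlier_pairs = {p.pair for p in outliers}
    assert not outlier_pairs & hk2_pairs, "training outliers leaked into test set"

    X_test = features.featurize_batch(hk2, layout, pr2, semtypes2)
    test_ids = [p.pair for p in hk2]

    contamination = (
        min(max(outlier_fraction, 1e-4), 0.5) if outlier_fraction > 0 else "auto"
    )
    fp = forest_params or anomaly.ForestParams(contamination=contamination, seed=seed)
    forest = anomaly.fit_isolation_forest(X_train_all, fp)
    forest_ranked = anomaly.score_pairs(forest, X_test, test_ids)
    forest_selected = anomaly.select_anomalies(forest_ranked)

    ocsvm_report: dict | None = None
    ocsvm_selected: set[Pair] | None = None
    op = ocsvm_params or anomaly.OneClassParams(nu=max(outlier_fraction, 0.01))
    try:
        ocsvm = anomaly.fit_one_class(X_train_norm, op)
        ocsvm_ranked = anomaly.score_pairs(ocsvm, X_test, test_ids)
        ocsvm_selected = anomaly.select_anomalies(ocsvm_ranked)
    except (ResourceLimitError, DegenerateInputError) as exc:
        log.warning("one-class SVM unavailable: %s", exc)
        ocsvm_report = {"error": type(exc).__name__, "message": str(exc)}

    gold = build_gold_standard(snap2, snap3)
    results = {
        "original": evaluate_f1(hk2_pairs, gold).to_dict(),
        "isolation_forest": evaluate_f1(forest_selected, gold).to_dict(),
    }
    if ocsvm_selected is not None:
        results["one_class_svm"] = evaluate_f1(ocsvm_selected, gold).to_dict()
    else:
        results["one_class_svm"] = ocsvm_report

    report = {
        "dates": {"train": labels[0], "test": labels[1], "eval": labels[2]},
        "filter_config": filter_config.to_dict(),
        "filter_order": [
            "min_frequency",
            "relation_blacklist",
            "outdegree",
            "linking_stoplist",
        ],
        "stoplist_sizes": {labels[0]: len(stop1), labels[1]: len(stop2)},
        "training": {
            "n_candidates": len(hk1),
            "n_normals": len(normals),
            "n_outliers": len(outliers),
            "outlier_fraction": outlier_fraction,
        },
        "models": {
            "isolation_forest": forest.params,
            "one_class_svm": (
                ocsvm_report if ocsvm_selected is None else ocsvm.params
            ),
        },
        "seed": seed,
        "no_leakage": True,
        "results": results,
    }
    # round-trip through JSON so the report is guaranteed serializable
    return json.loads(json.dumps(report))
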