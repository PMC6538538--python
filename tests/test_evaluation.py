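"""Timeslice gold standards, F-measure algebra, paired t-tests, and the
end-to-end experiment orchestration."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lbdkit import evaluation
from lbdkit.errors import ConfigError, DataError, DegenerateInputError
from tests.conftest import make_snapshot

# F columns of the five train/test/eval splits reported for the
# thesaurus-relations experiments (original, isolation forest, one-class)
F_ORIG = [0.0049, 0.0046, 0.0026, 0.0025, 0.0043]
F_ISO = [0.0055, 0.0068, 0.0045, 0.0030, 0.0048]
F_ONE = [0.0099, 0.0093, 0.0050, 0.0051, 0.0074]


# ---------------------------------------------------------------------------
# gold standard and training labels
# ---------------------------------------------------------------------------


def test_gold_standard_is_set_difference_of_known_pairs():
    earlier = make_snapshot([("a", "r", "b")], date="d2")
    later = make_snapshot([("a", "r", "b"), ("a", "r", "c")], date="d3")
    gs = evaluation.build_gold_standard(earlier, later)
    assert gs.pairs == {("a", "c")}
    assert gs.window == ("d2", "d3")


def test_gold_standard_empty_when_later_is_subset():
    earlier = make_snapshot([("a", "r", "b"), ("a", "r", "c")], date="d2")
    later = make_snapshot([("a", "r", "b")], date="d3")
    assert evaluation.build_gold_standard(earlier, later).pairs == frozenset()


def test_gold_standard_rejects_identical_dates():
    snap = make_snapshot([("a", "r", "b")])
    with pytest.raises(ConfigError):
        evaluation.build_gold_standard(snap, snap)


def test_gold_standard_equals_planted_plus_background(artifacts):
    gt = artifacts.fixture.ground_truth
    gs = evaluation.build_gold_standard(artifacts.snap2, artifacts.snap3)
    expected = {tuple(p) for p in gt["planted_pairs"]} | {
        tuple(p) for p in gt["background_confirmations"]["date3"]
    }
    assert gs.pairs == expected


def test_training_outliers_are_exactly_the_confirmed_candidates(artifacts):
    normals, outliers = evaluation.label_training_outliers(
        artifacts.hk1, artifacts.snap2
    )
    gt = artifacts.fixture.ground_truth
    assert {p.pair for p in outliers} == {
        tuple(p) for p in gt["background_confirmations"]["date2"]
    }
    assert len(normals) + len(outliers) == len(artifacts.hk1)
    assert not {p.pair for p in normals} & {p.pair for p in outliers}


def test_unconfirmed_candidates_are_all_normal():
    snap1 = make_snapshot([("a", "r", "b"), ("b", "r", "c")], date="d1")
    snap2 = make_snapshot([("a", "r", "b"), ("b", "r", "c")], date="d2")
    from lbdkit import discovery

    hk = discovery.abc_closure(snap1)
    normals, outliers = evaluation.label_training_outliers(hk, snap2)
    assert outliers == []
    assert len(normals) == len(hk)


# ---------------------------------------------------------------------------
# F-measure
# ---------------------------------------------------------------------------


def test_f1_perfect_and_disjoint():
    gs = evaluation.GoldStandard(frozenset({("a", "b"), ("c", "d")}), ("d2", "d3"))
    perfect = evaluation.evaluate_f1({("a", "b"), ("c", "d")}, gs)
    assert perfect.f1 == 1.0
    disjoint = evaluation.evaluate_f1({("x", "y")}, gs)
    assert disjoint.f1 == 0.0
    assert disjoint.tp == 0


def test_f1_at_reported_large_scale_counts():
    """The F identity reproduces the printed value for the largest split:
    5,748,834 proposed pairs, 24,772 gold pairs, F = 0.0043."""
    f1 = evaluation.f1_from_counts(5_748_834, 24_772, tp=12_413)
    assert f1 == pytest.approx(0.0043, abs=5e-5)


def test_empty_gold_standard_is_fatal():
    gs = evaluation.GoldStandard(frozenset(), ("d2", "d3"))
    with pytest.raises(DataError):
        evaluation.evaluate_f1({("a", "b")}, gs)


@settings(max_examples=200, deadline=None)
@given(
    n_pred=st.integers(0, 10_000),
    n_gold=st.integers(1, 10_000),
    tp_frac=st.floats(0, 1),
)
def test_f1_identity_holds_algebraically(n_pred, n_gold, tp_frac):
    tp = int(min(n_pred, n_gold) * tp_frac)
    f1 = evaluation.f1_from_counts(n_pred, n_gold, tp)
    precision = tp / n_pred if n_pred else 0.0
    recall = tp / n_gold
    expected = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    assert f1 == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# paired t-test
# ---------------------------------------------------------------------------


def test_paired_ttest_on_reported_f_columns():
    """One-sided paired t on the printed per-split F values reproduces the
    reported significance levels (recomputed from rounded inputs)."""
    assert evaluation.paired_ttest(F_ORIG, F_ONE).p_value == pytest.approx(
        0.00138, abs=5e-5
    )
    assert evaluation.paired_ttest(F_ORIG, F_ISO).p_value == pytest.approx(
        0.0192, abs=5e-4
    )
    assert evaluation.paired_ttest(F_ISO, F_ONE).p_value == pytest.approx(
        0.00886, abs=5e-5
    )


def test_paired_ttest_symmetric_input_gives_half():
    r = evaluation.paired_ttest([1.0, 2.0], [2.0, 1.0])
    assert r.t_statistic == pytest.approx(0.0)
    assert r.p_value == pytest.approx(0.5)


def test_paired_ttest_matches_scipy_reference():
    rng = np.random.default_rng(0)
    for _ in range(10):
        a = rng.normal(size=8)
        b = a + rng.normal(scale=0.5, size=8)
        ours = evaluation.paired_ttest(a, b)
        ref = stats.ttest_rel(b, a, alternative="greater")
        assert ours.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        two = evaluation.paired_ttest(a, b, tail="two-sided")
        ref2 = stats.ttest_rel(b, a)
        assert two.p_value == pytest.approx(ref2.pvalue, abs=1e-10)
        if ours.t_statistic > 0:
            assert ours.p_value == pytest.approx(two.p_value / 2, abs=1e-12)


def test_paired_ttest_degenerate_differences_error():
    with pytest.raises(DegenerateInputError):
        evaluation.paired_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


def test_paired_ttest_needs_two_observations():
    with pytest.raises(DataError):
        evaluation.paired_ttest([1.0], [2.0])


# ---------------------------------------------------------------------------
# end-to-end experiment
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def report(artifacts):
    s1 = artifacts.fixture.snapshot("date1")
    s2 = artifacts.fixture.snapshot("date2")
    s3 = artifacts.fixture.snapshot("date3")
    return evaluation.run_timeslice_experiment(
        s1, s2, s3, filter_config=artifacts.fixture.filters, seed=1
    )


def test_experiment_report_structure_and_leakage_flag(report):
    assert report["no_leakage"] is True
    for system in ("original", "isolation_forest", "one_class_svm"):
        res = report["results"][system]
        assert {"tp", "precision", "recall", "f1", "hk_size", "gs_size"} <= set(res)
    assert report["filter_order"][0] == "min_frequency"
    assert report["training"]["n_outliers"] > 0


def test_forest_selection_beats_unranked_f1(report):
    assert (
        report["results"]["isolation_forest"]["f1"]
        > report["results"]["original"]["f1"]
    )


def test_experiment_is_deterministic(artifacts):
    import json

    snaps = artifacts.fixture.snapshots()
    r1 = evaluation.run_timeslice_experiment(
        *snaps, filter_config=artifacts.fixture.filters, seed=5
    )
    r2 = evaluation.run_timeslice_experiment(
        *snaps, filter_config=artifacts.fixture.filters, seed=5
    )
    assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)


def test_experiment_requires_distinct_dates(artifacts):
    s1 = artifacts.fixture.snapshot("date1")
    with pytest.raises(ConfigError):
        evaluation.run_timeslice_experiment(
            s1, s1, s1, filter_config=artifacts.fixture.filters
        )


def test_experiment_without_planted_links_completes():
    """Gold standard from background growth alone still evaluates."""
    from dataclasses import replace

    from lbdkit import synthetic

    spec = replace(
        synthetic.SyntheticSpec(),
        n_concepts=400,
        n_planted_interesting=0,
        hub_count=1,
        hub_outdegree=60,
        stop_term_fanin=25,
        stop_term_fanout=25,
        n_isa_pairs=5,
        n_specialist_concepts=15,
        outdegree_max=40,
        lt_freq_max=400,
        seed=3,
    )
    fx = synthetic.generate_fixture(spec)
    report = evaluation.run_timeslice_experiment(
        *fx.snapshots(), filter_config=fx.filters, seed=0
    )
    assert report["results"]["original"]["gs_size"] > 0
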