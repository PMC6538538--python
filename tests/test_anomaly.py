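"""Detector fitting, scoring, selection, and decision-point inspection."""

from __future__ import annotations

import numpy as np
import pytest

from lbdkit import anomaly, features, kg
from lbdkit.errors import DataError, DegenerateInputError, ResourceLimitError


@pytest.fixture(scope="module")
def gaussian_cloud():
    rng = np.random.default_rng(0)
    return rng.normal(size=(500, 4))


def _ids(n):
    return [(f"A{i:05d}", f"C{i:05d}") for i in range(n)]


# ---------------------------------------------------------------------------
# isolation forest
# ---------------------------------------------------------------------------


def test_forest_puts_planted_far_outliers_on_top():
    rng = np.random.default_rng(1)
    background = rng.normal(size=(1000, 6))
    outliers = rng.normal(size=(10, 6)) + 12.0
    X = np.vstack([background, outliers])
    model = anomaly.fit_isolation_forest(X, anomaly.ForestParams(seed=0))
    ranked = anomaly.score_pairs(model, X, _ids(len(X)))
    top2pct = {pid for pid, _ in ranked.pairs[: len(X) // 50]}
    planted = set(_ids(len(X))[1000:])
    assert planted <= top2pct


def test_forest_is_deterministic_under_fixed_seed(gaussian_cloud):
    m1 = anomaly.fit_isolation_forest(gaussian_cloud, anomaly.ForestParams(seed=3))
    m2 = anomaly.fit_isolation_forest(gaussian_cloud, anomaly.ForestParams(seed=3))
    assert np.array_equal(
        m1.anomaly_scores(gaussian_cloud), m2.anomaly_scores(gaussian_cloud)
    )


def test_forest_scoring_duplicated_queries_keeps_ranking(gaussian_cloud):
    model = anomaly.fit_isolation_forest(
        gaussian_cloud, anomaly.ForestParams(seed=0)
    )
    single = model.anomaly_scores(gaussian_cloud)
    doubled = model.anomaly_scores(np.vstack([gaussian_cloud, gaussian_cloud]))
    assert np.array_equal(doubled[: len(single)], single)
    assert np.array_equal(doubled[len(single) :], single)


def test_forest_single_distinct_vector_is_fatal():
    X = np.ones((50, 3))
    with pytest.raises(DataError, match="distinct"):
        anomaly.fit_isolation_forest(X, anomaly.ForestParams(seed=0))


def test_forest_score_anti_monotone_along_axes():
    """Pushing a point outward from the data never makes it look less
    anomalous (2-D cloud, probes along each axis)."""
    rng = np.random.default_rng(4)
    X = rng.normal(size=(800, 2))
    model = anomaly.fit_isolation_forest(X, anomaly.ForestParams(seed=0))
    lo, hi = X.min(), X.max()
    for axis in (0, 1):
        probes = np.zeros((12, 2))
        probes[:, axis] = np.linspace(hi, hi + 20, 12)
        scores = model.anomaly_scores(probes)
        assert (np.diff(scores) >= -1e-9).all()
        probes[:, axis] = np.linspace(lo, lo - 20, 12)
        scores = model.anomaly_scores(probes)
        assert (np.diff(scores) >= -1e-9).all()


# ---------------------------------------------------------------------------
# one-class SVM
# ---------------------------------------------------------------------------


def test_one_class_accepts_centroid_rejects_far_point(gaussian_cloud):
    model = anomaly.fit_one_class(gaussian_cloud, anomaly.OneClassParams(nu=0.05))
    centroid = gaussian_cloud.mean(axis=0, keepdims=True)
    far = centroid.copy()
    far[0, 0] += 10.0  # ten sigma out on one coordinate
    assert not model.flags(centroid)[0]
    assert model.flags(far)[0]


def test_one_class_degenerate_training_data_is_explicit_error():
    X = np.ones((40, 3))
    with pytest.raises(DegenerateInputError):
        anomaly.fit_one_class(X)


def test_one_class_memory_guard_names_matrix_size():
    X = np.zeros((2000, 3))
    X[0, 0] = 1.0
    params = anomaly.OneClassParams(max_train_bytes=1024)
    with pytest.raises(ResourceLimitError, match="n=2000"):
        anomaly.fit_one_class(X, params)


def test_one_class_boundary_independent_of_row_order(gaussian_cloud):
    rng = np.random.default_rng(5)
    perm = rng.permutation(len(gaussian_cloud))
    params = anomaly.OneClassParams(nu=0.1, tol=1e-9)
    m1 = anomaly.fit_one_class(gaussian_cloud, params)
    m2 = anomaly.fit_one_class(gaussian_cloud[perm], params)
    probes = gaussian_cloud[:20]
    assert m1.anomaly_scores(probes) == pytest.approx(
        m2.anomaly_scores(probes), abs=1e-5
    )


# ---------------------------------------------------------------------------
# ranking and selection
# ---------------------------------------------------------------------------


def test_score_pairs_empty_and_single(gaussian_cloud):
    model = anomaly.fit_isolation_forest(
        gaussian_cloud, anomaly.ForestParams(seed=0)
    )
    empty = anomaly.score_pairs(model, np.empty((0, 4)), [])
    assert empty.pairs == []
    one = anomaly.score_pairs(model, gaussian_cloud[:1], _ids(1))
    assert len(one.pairs) == 1


def test_score_pairs_rejects_width_mismatch(gaussian_cloud):
    model = anomaly.fit_isolation_forest(
        gaussian_cloud, anomaly.ForestParams(seed=0)
    )
    with pytest.raises(DataError, match="width"):
        anomaly.score_pairs(model, np.zeros((3, 5)), _ids(3))


def test_ranking_sorted_with_stable_tie_break(gaussian_cloud):
    model = anomaly.fit_isolation_forest(
        gaussian_cloud, anomaly.ForestParams(seed=0)
    )
    X = np.vstack([gaussian_cloud[:5]] * 2)  # forced score ties
    ranked = anomaly.score_pairs(model, X, _ids(10))
    scores = [s for _, s in ranked.pairs]
    assert scores == sorted(scores, reverse=True)
    for (pid1, s1), (pid2, s2) in zip(ranked.pairs, ranked.pairs[1:]):
        if s1 == s2:
            assert pid1 < pid2


def test_select_top_k_and_native_threshold(gaussian_cloud):
    model = anomaly.fit_isolation_forest(
        gaussian_cloud, anomaly.ForestParams(seed=0)
    )
    ranked = anomaly.score_pairs(model, gaussian_cloud, _ids(len(gaussian_cloud)))
    assert anomaly.select_anomalies(ranked, ("top_k", len(gaussian_cloud))) == {
        pid for pid, _ in ranked.pairs
    }
    assert anomaly.select_anomalies(ranked, ("top_k", 0)) == set()
    native = anomaly.select_anomalies(ranked, "native")
    assert native == ranked.selected_pairs()


def test_contamination_sets_selected_fraction():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(10_000, 5))
    model = anomaly.fit_isolation_forest(
        X, anomaly.ForestParams(contamination=0.01, seed=0)
    )
    ranked = anomaly.score_pairs(model, X, _ids(len(X)))
    n_sel = len(anomaly.select_anomalies(ranked))
    assert 80 <= n_sel <= 120  # ~1% of 10,000 up to threshold rounding


# ---------------------------------------------------------------------------
# decision points
# ---------------------------------------------------------------------------


def _toy_layout():
    inv = kg.SemanticTypeInventory(["dsyn", "fndg"])
    return features.FeatureLayout(inv, ["may_treat"])  # length 8


def test_decision_points_find_the_only_informative_feature():
    rng = np.random.default_rng(7)
    layout = _toy_layout()
    X = np.zeros((400, layout.total_length))
    X[:, 0] = rng.integers(1, 40, size=400)  # only slot 0 varies
    model = anomaly.fit_isolation_forest(X, anomaly.ForestParams(seed=0))
    points = anomaly.inspect_decision_points(model, layout, depth_cutoff=2)
    assert points[0][0] == "number of linking terms"


def test_decision_points_depth_zero_counts_roots_only():
    rng = np.random.default_rng(8)
    layout = _toy_layout()
    X = rng.random((300, layout.total_length))
    model = anomaly.fit_isolation_forest(X, anomaly.ForestParams(seed=0))
    roots = anomaly.inspect_decision_points(
        model, layout, depth_cutoff=0, minority_frac=0.5
    )
    assert sum(c for _, c in roots) == 100  # one root per tree
    deeper = anomaly.inspect_decision_points(
        model, layout, depth_cutoff=2, minority_frac=0.5
    )
    assert sum(c for _, c in deeper) > 100


def test_decision_points_recover_planted_outlier_slots():
    rng = np.random.default_rng(9)
    layout = _toy_layout()
    X = np.zeros((1000, layout.total_length))
    X[:, 0] = 1.0
    out_rows = rng.choice(1000, size=15, replace=False)
    X[out_rows, 2] = 0.5   # A:fndg slot
    X[out_rows, 7] = 0.5   # relation slot
    X += rng.normal(scale=1e-3, size=X.shape)
    model = anomaly.fit_isolation_forest(X, anomaly.ForestParams(seed=0))
    points = anomaly.inspect_decision_points(model, layout, depth_cutoff=2)
    top3 = {name for name, _ in points[:3]}
    assert {"A:fndg", "relation:may_treat"} <= top3


def test_decision_points_require_a_forest(gaussian_cloud):
    model = anomaly.fit_one_class(gaussian_cloud)
    with pytest.raises(DataError, match="isolation forest"):
        anomaly.inspect_decision_points(model, _toy_layout())


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def test_model_round_trip_with_layout_hash(tmp_path, gaussian_cloud):
    layout = _toy_layout()
    X = np.pad(gaussian_cloud, ((0, 0), (0, layout.total_length - 4)))
    model = anomaly.fit_isolation_forest(X, anomaly.ForestParams(seed=0))
    path = tmp_path / "model.joblib"
    anomaly.save_model(model, path, layout)
    back = anomaly.load_model(path, layout)
    assert back.algorithm == "isolation_forest"
    probe = np.zeros((3, model.n_features))
    assert np.array_equal(back.anomaly_scores(probe), model.anomaly_scores(probe))
    other_layout = features.FeatureLayout(
        kg.SemanticTypeInventory(["x", "y"]), ["q"]
    )
    with pytest.raises(DataError, match="layout"):
        anomaly.load_model(path, other_layout)
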