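"""Anomaly-detection re-ranking of hidden-knowledge feature vectors.

Two detectors are supported.  The isolation forest partitions the data
with an ensemble of random trees and scores points by average isolation
path length: the numerically rare, differently-shaped vectors -- the
interesting candidates -- isolate near the root.  It is trained
unsupervised on all candidates, with the contamination rate set from the
observed fraction of training-window confirmations.  The one-class SVM is
a novelty detector: it is fit on the uninteresting (unconfirmed) majority
only and classifies new vectors as similar or different.  Its kernel
matrix grows quadratically in the training size, so fitting is guarded by
an explicit memory budget that raises a resource error instead of
exhausting RAM.

Ranking output is deterministic: scores are sorted most-anomalous-first
with ties broken by pair identifier.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import IsolationForest
from sklearn.svm import OneClassSVM

from .errors import DataError, DegenerateInputError, ResourceLimitError
from .features import FeatureLayout

log = logging.getLogger(__name__)

__all__ = [
    "ForestParams",
    "OneClassParams",
    "AnomalyModel",
    "RankedPairs",
    "fit_isolation_forest",
    "fit_one_class",
    "score_pairs",
    "select_anomalies",
    "inspect_decision_points",
    "save_model",
    "load_model",
]

PairId = tuple[str, str]


@dataclass(frozen=True)
class ForestParams:
    """Isolation-forest settings: 100 trees, subsample 256, explicit seed."""

    n_trees: int = 100
    subsample: int = 256
    contamination: float | str = "auto"
    seed: int = 0


@dataclass(frozen=True)
class OneClassParams:
    """One-class SVM settings (radial-basis kernel).

    ``nu`` bounds the training-outlier fraction; callers normally set it to
    max(observed outlier fraction, 0.01).  ``gamma='scale'`` sets the
    kernel width to 1 / (n_features * feature variance).
    ``max_train_bytes`` caps the implied n^2 kernel matrix; exceeding it
    raises :class:`ResourceLimitError` before any allocation.
    """

    kernel: str = "rbf"
    nu: float = 0.01
    gamma: float | str = "scale"
    tol: float = 1e-3
    max_train_bytes: int = 8 * 1024**3

    def __post_init__(self) -> None:
        if not 0 < self.nu <= 1:
            raise ValueError(f"nu must be in (0, 1], got {self.nu}")


@dataclass
class AnomalyModel:
    """A fitted detector plus the metadata needed to reproduce it."""

    algorithm: str  # 'isolation_forest' | 'one_class_svm'
    params: dict
    estimator: object
    n_features: int
    training_outlier_fraction: float = 0.0

    def anomaly_scores(self, X) -> np.ndarray:
        """Higher = more anomalous (negated sklearn score_samples)."""
        if X.shape[1] != self.n_features:
            raise DataError(
                f"feature width {X.shape[1]} does not match the model's "
                f"{self.n_features}"
            )
        return -np.asarray(self.estimator.score_samples(X))

    def flags(self, X) -> np.ndarray:
        """Native-threshold anomaly mask (True = flagged anomalous)."""
        if X.shape[1] != self.n_features:
            raise DataError(
                f"feature width {X.shape[1]} does not match the model's "
                f"{self.n_features}"
            )
        return np.asarray(self.estimator.predict(X)) == -1


@dataclass
class RankedPairs:
    """Scored candidates sorted most-anomalous-first, with a selection mask."""

    pairs: list[tuple[PairId, float]]
    selected: np.ndarray  # bool mask aligned with `pairs`

    def __post_init__(self) -> None:
        if len(self.selected) != len(self.pairs):
            raise DataError("selection mask length does not match ranking length")

    def selected_pairs(self) -> set[PairId]:
        return {pid for (pid, _), sel in zip(self.pairs, self.selected) if sel}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tscore\tselected\n")
            for (pid, score), sel in zip(self.pairs, self.selected):
                fh.write(f"{pid[0]}\t{pid[1]}\t{score:.17g}\t{int(sel)}\n")


def _n_distinct_rows(X) -> int:
    dense = X.toarray() if sp.issparse(X) else np.asarray(X)
    return len({r.tobytes() for r in np.ascontiguousarray(dense)})


def fit_isolation_forest(X, params: ForestParams) -> AnomalyModel:
    """Fit the random-partition tree ensemble on all candidate vectors.

    Fitting memory is bounded by the subsample size and tree count, not by
    the candidate count, which is what makes the forest usable at
    full-vocabulary scale.
    """
    n = X.shape[0]
    if n < 2 or _n_distinct_rows(X) < 2:
        raise DataError(
            "isolation forest needs at least two distinct training vectors"
        )
    est = IsolationForest(
        n_estimators=params.n_trees,
        max_samples=min(params.subsample, n),
        contamination=params.contamination,
        random_state=params.seed,
    )
    est.fit(X)
    frac = (
        params.contamination if isinstance(params.contamination, float) else 0.0
    )
    return AnomalyModel(
        algorithm="isolation_forest",
        params={
            "n_trees": params.n_trees,
            "subsample": params.subsample,
            "contamination": params.contamination,
            "seed": params.seed,
        },
        estimator=est,
        n_features=X.shape[1],
        training_outlier_fraction=frac,
    )


def fit_one_class(X, params: OneClassParams = OneClassParams()) -> AnomalyModel:
    """Fit the one-class SVM on normal (uninteresting) vectors only.

    The implied kernel matrix is n^2 doubles; if that exceeds the configured
    budget a :class:`ResourceLimitError` is raised naming the size, so a
    driver can skip the model (the documented large-scale failure mode)
    rather than crash.  Zero-variance training data has no meaningful
    boundary and raises :class:`DegenerateInputError`.
    """
    n = X.shape[0]
    if n == 0:
        raise DataError("one-class SVM needs at least one training vector")
    kernel_bytes = 8 * n * n
    if kernel_bytes > params.max_train_bytes:
        raise ResourceLimitError(
            f"one-class SVM kernel matrix for n={n} would need "
            f"{kernel_bytes / 1024**3:.1f} GiB "
            f"(budget {params.max_train_bytes / 1024**3:.1f} GiB)"
        )
    if _n_distinct_rows(X) < 2:
        raise DegenerateInputError(
            "one-class SVM training data has zero variance (all vectors "
            "identical); no boundary can be estimated"
        )
    est = OneClassSVM(kernel=params.kernel, nu=params.nu, gamma=params.gamma,
                      tol=params.tol)
    est.fit(X)
    return AnomalyModel(
        algorithm="one_class_svm",
        params={"kernel": params.kernel, "nu": params.nu, "gamma": str(params.gamma)},
        estimator=est,
        n_features=X.shape[1],
        training_outlier_fraction=params.nu,
    )


def score_pairs(model: AnomalyModel, X, pair_ids: Sequence[PairId]) -> RankedPairs:
    """Rank candidates by anomaly score, most anomalous first.

    Ties are broken by pair id so repeated runs produce identical files.
    The selection mask uses the model's native decision threshold.
    """
    if len(pair_ids) != X.shape[0]:
        raise DataError("pair id list does not match feature matrix rows")
    if X.shape[0] == 0:
        return RankedPairs(pairs=[], selected=np.zeros(0, dtype=bool))
    scores = model.anomaly_scores(X)
    flags = model.flags(X)
    order = sorted(range(len(pair_ids)), key=lambda i: (-scores[i], pair_ids[i]))
    return RankedPairs(
        pairs=[(pair_ids[i], float(scores[i])) for i in order],
        selected=flags[order],
    )


def select_anomalies(
    ranked: RankedPairs, policy: str | tuple[str, int] = "native"
) -> set[PairId]:
    """The anomalous subset under a selection policy.

    ``'native'`` uses the detector's own threshold (the mask recorded at
    scoring time); ``('top_k', k)`` takes the k most anomalous.
    """
    if policy == "native":
        return ranked.selected_pairs()
    if isinstance(policy, tuple) and policy[0] == "top_k":
        k = policy[1]
        return {pid for pid, _ in ranked.pairs[:k]}
    raise ValueError(f"unknown selection policy: {policy!r}")


def inspect_decision_points(
    model: AnomalyModel,
    layout: FeatureLayout,
    depth_cutoff: int = 2,
    minority_frac: float = 0.1,
) -> list[tuple[str, int]]:
    """Rank features by how often they isolate a minority near tree roots.

    Isolation trees draw split features uniformly at random, so raw split
    frequency says nothing about the data; what marks a feature as an
    anomaly decision point is that, when drawn, its split strands a small
    minority of the node's samples close to the root.  A node at depth <=
    ``depth_cutoff`` counts towards its feature when its smaller child
    holds at most ``minority_frac`` of the node's training samples.
    Returned as (slot name, count) sorted most frequent first, e.g.
    [('number of linking terms', 97), ('LT:st014', 41), ...].
    """
    if model.algorithm != "isolation_forest":
        raise DataError("decision-point inspection requires an isolation forest")
    counts: dict[int, int] = {}
    for tree in model.estimator.estimators_:
        t = tree.tree_
        stack = [(0, 0)]  # (node, depth)
        while stack:
            node, depth = stack.pop()
            if depth > depth_cutoff or t.children_left[node] == -1:
                continue
            left, right = t.children_left[node], t.children_right[node]
            n_here = t.n_node_samples[node]
            n_minor = min(t.n_node_samples[left], t.n_node_samples[right])
            if n_minor <= minority_frac * n_here:
                f = int(t.feature[node])
                counts[f] = counts.get(f, 0) + 1
            stack.append((left, depth + 1))
            stack.append((right, depth + 1))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(layout.slot_name(f), c) for f, c in ranked]


# ---------------------------------------------------------------------------
# Persistence: binary artifact + JSON sidecar
# ---------------------------------------------------------------------------


def _layout_hash(layout: FeatureLayout) -> str:
    payload = json.dumps([list(layout.semtypes.types), list(layout.relations)])
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_model(model: AnomalyModel, path: str | Path, layout: FeatureLayout) -> None:
    path = Path(path)
    joblib.dump(model.estimator, path)
    sidecar = {
        "format_version": 1,
        "algorithm": model.algorithm,
        "params": model.params,
        "n_features": model.n_features,
        "training_outlier_fraction": model.training_outlier_fraction,
        "layout_hash": _layout_hash(layout),
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def load_model(path: str | Path, layout: FeatureLayout | None = None) -> AnomalyModel:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not path.exists() or not sidecar_path.exists():
        raise DataError(f"model artifact or sidecar missing at {path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    if layout is not None and sidecar["layout_hash"] != _layout_hash(layout):
        raise DataError("model was trained under a different feature layout")
    return AnomalyModel(
        algorithm=sidecar["algorithm"],
        params=sidecar["params"],
        estimator=joblib.load(path),
        n_features=sidecar["n_features"],
        training_outlier_fraction=sidecar["training_outlier_fraction"],
    )
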