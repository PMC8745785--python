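"""The three classifier families applied to bag-of-features histograms.

Families: RBF support vector machine, k-nearest neighbors, and the two
ensembles used for apnea-window classification — bagged decision trees and
a random-subspace KNN ensemble of 30 learners combined by majority vote.

Hyperparameter optimization uses nested stratified cross-validation with a
grid search: inner folds select hyperparameters on training data only,
outer folds report unbiased accuracy/sensitivity/specificity.

The positive class is ``A`` (apnea) throughout, so sensitivity is the
apnea detection rate.  KNN voting ties resolve to the lexicographically
first class label (``A``); default grids use odd k so ties cannot arise.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .bof import BofVector, feature_matrix
from .errors import TrainingError

FAMILIES = ("svm", "knn", "el_bagged_trees", "el_subspace_knn")
SUBSPACE_KNN_LEARNERS = 30
BAGGED_TREES_LEARNERS = 30

#: Default hyperparameter grids (Mahalanobis KNN is available by explicit
#: request only: covariance of sparse histograms is routinely singular).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {"C": [0.1, 1, 10, 100], "gamma": ["scale", 0.1, 1, 10]},
    "knn": {"n_neighbors": [1, 3, 5, 11], "metric": ["euclidean", "cosine"]},
    "el_bagged_trees": {"n_estimators": [BAGGED_TREES_LEARNERS]},
    "el_subspace_knn": {"n_neighbors": [1, 3, 5]},
}

_ALLOWED_KEYS = {
    "svm": {"C", "gamma", "kernel"},
    "knn": {"n_neighbors", "metric"},
    "el_bagged_trees": {"n_estimators", "max_samples"},
    "el_subspace_knn": {"n_neighbors", "n_estimators", "metric"},
}


@dataclass(frozen=True)
class ClassifierSpec:
    family: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        bad = set(self.hyperparams) - _ALLOWED_KEYS[self.family]
        if bad:
            raise ValueError(
                f"unrecognized hyperparameters for {self.family}: {sorted(bad)}"
            )

    def replace_params(self, **params) -> "ClassifierSpec":
        return ClassifierSpec(self.family, {**self.hyperparams, **params}, self.seed)


class _HardVoteKNN(KNeighborsClassifier):
    """KNN without predict_proba, so a bagging ensemble combines members by
    hard majority vote (the subspace-KNN combination rule) instead of
    averaged neighbor fractions."""

    @property
    def predict_proba(self):
        raise AttributeError("hard-vote member: no predict_proba")


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object  # fitted sklearn estimator
    classes: tuple[str, str]  # (negative, positive) = (N, A)
    n_features: int
    training_fingerprint: str


def build_estimator(spec: ClassifierSpec, n_features: int):
    """Instantiate the sklearn estimator for a spec (unfitted)."""
    hp = dict(spec.hyperparams)
    if spec.family == "svm":
        return SVC(
            kernel=hp.get("kernel", "rbf"),
            C=hp.get("C", 1.0),
            gamma=hp.get("gamma", "scale"),
            random_state=spec.seed,
        )
    if spec.family == "knn":
        return KNeighborsClassifier(
            n_neighbors=hp.get("n_neighbors", 5),
            metric=hp.get("metric", "euclidean"),
        )
    if spec.family == "el_bagged_trees":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=spec.seed),
            n_estimators=hp.get("n_estimators", BAGGED_TREES_LEARNERS),
            max_samples=hp.get("max_samples", 1.0),
            bootstrap=True,
            random_state=spec.seed,
        )
    if spec.family == "el_subspace_knn":
        return BaggingClassifier(
            estimator=_HardVoteKNN(
                n_neighbors=hp.get("n_neighbors", 5),
                metric=hp.get("metric", "euclidean"),
            ),
            n_estimators=hp.get("n_estimators", SUBSPACE_KNN_LEARNERS),
            bootstrap=False,
            max_samples=1.0,
            bootstrap_features=False,
            max_features=max(1, math.ceil(n_features / 2)),
            random_state=spec.seed,
        )
    raise ValueError(spec.family)  # pragma: no cover


def _as_xy(features, labels=None):
    if labels is not None:
        return np.asarray(features, dtype=np.float64), np.asarray(labels)
    if len(features) and isinstance(features[0], BofVector):
        X, y, _, _ = feature_matrix(features)
        return X, y
    raise TypeError("pass a list of BofVector, or (array, labels)")


def _fingerprint(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(",".join(map(str, y)).encode())
    h.update(json.dumps([spec.family, spec.hyperparams, spec.seed], sort_keys=True).encode())
    return h.hexdigest()[:16]


def train(
    features: Sequence[BofVector] | np.ndarray,
    spec: ClassifierSpec,
    labels: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit one classifier; deterministic given the spec's seed."""
    X, y = _as_xy(features, labels)
    counts = {c: int(n) for c, n in zip(*np.unique(y, return_counts=True))}
    if len(counts) < 2:
        raise TrainingError(
            f"training set contains a single class {list(counts)}; refusing to fit"
        )
    if min(counts.values()) < 2:
        raise TrainingError(f"need >= 2 examples per class, got {counts}")
    est = build_estimator(spec, X.shape[1])
    est.fit(X, y)
    return TrainedModel(
        spec=spec,
        estimator=est,
        classes=("N", "A"),
        n_features=X.shape[1],
        training_fingerprint=_fingerprint(X, y, spec),
    )


def predict(
    model: TrainedModel, features: Sequence[BofVector] | np.ndarray
) -> list[str]:
    """Predict N/A labels; order preserved; empty input is legal."""
    if len(features) == 0:
        return []
    if isinstance(features[0], BofVector):
        X = np.vstack([v.values for v in features])
    else:
        X = np.asarray(features, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
    if X.shape[1] != model.n_features:
        raise TrainingError(
            f"feature dimension {X.shape[1]} != training dimension {model.n_features}"
        )
    return list(model.estimator.predict(X))


# ---------------------------------------------------------------------------
# Nested cross-validated grid search
# ---------------------------------------------------------------------------


@dataclass
class OuterFoldResult:
    fold: int
    best_params: dict
    inner_mean_accuracy: float
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class NestedCVReport:
    family: str
    per_fold: list[OuterFoldResult]
    mean_accuracy: float
    mean_sensitivity: float
    mean_specificity: float


def _fold_metrics(y_true, y_pred):
    from .evaluation import confusion, metrics

    return metrics(confusion(y_true, y_pred))


def grid_search_nested(
    features,
    spec: ClassifierSpec,
    grid: dict[str, list] | None = None,
    outer_k: int = 5,
    inner_k: int = 5,
    seed: int = 0,
    labels=None,
) -> NestedCVReport:
    """Nested stratified k-fold grid search.

    Inner folds (over each outer training split only) score every grid
    point by mean accuracy; the best point (ties break to grid order) is
    refit on the outer training split and scored on the held-out outer
    fold, giving an unbiased performance estimate.
    """
    X, y = _as_xy(features, labels)
    grid = grid if grid is not None else DEFAULT_GRIDS[spec.family]
    candidates = list(ParameterGrid(grid))
    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed + 1)
    _, class_counts = np.unique(y, return_counts=True)
    if class_counts.min() < outer_k:
        raise TrainingError(
            f"minority class has {class_counts.min()} samples < outer_k={outer_k}"
        )
    results = []
    for fold, (tr, te) in enumerate(outer.split(X, y)):
        Xtr, ytr = X[tr], y[tr]
        best_params, best_score = None, -np.inf
        for params in candidates:
            cand = spec.replace_params(**params)
            scores = []
            for itr, ite in inner.split(Xtr, ytr):
                if len(np.unique(ytr[itr])) < 2 or len(np.unique(ytr[ite])) < 2:
                    raise TrainingError("inner fold lost a class; stratification failed")
                est = build_estimator(cand, X.shape[1])
                est.fit(Xtr[itr], ytr[itr])
                scores.append(float(np.mean(est.predict(Xtr[ite]) == ytr[ite])))
            score = float(np.mean(scores))
            if score > best_score:
                best_params, best_score = params, score
        model = train(Xtr, spec.replace_params(**best_params), labels=ytr)
        acc, sens, spec_ = _fold_metrics(y[te], np.asarray(predict(model, X[te])))
        results.append(
            OuterFoldResult(fold, best_params, best_score, acc, sens, spec_)
        )
    return NestedCVReport(
        family=spec.family,
        per_fold=results,
        mean_accuracy=float(np.mean([r.accuracy for r in results])),
        mean_sensitivity=float(np.nanmean([r.sensitivity for r in results])),
        mean_specificity=float(np.nanmean([r.specificity for r in results])),
    )
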