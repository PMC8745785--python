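"""Classification metrics and the three validation schemes.

Metrics follow the condition-positive convention with apnea (``A``) as the
positive class:

    accuracy    = (TP + TN) / (P + N)      P = TP + FN, N = FP + TN
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

A zero denominator yields NaN with a warning — never a silent 0.

Schemes:

* ``kfold``   — stratified 5-fold CV at the spectrogram (window) level: a
  subject's windows may span folds, deliberately matching the
  window-level protocol; the aggregate is the unweighted mean over folds.
* ``losocv``  — leave-one-subject-out: one fold per subject; a test
  subject whose windows are single-class yields NaN for the undefined
  metric, which is excluded from that metric's average (the
  include-as-zero variant is also reported, since per-subject tables in
  the literature print 0 for such rows).
* ``stage_stratified`` — independent evaluation within REM and NREM
  strata, with optional seeded random undersampling of the majority
  class.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifiers import ClassifierSpec, predict, train
from .errors import EvaluationError

POSITIVE = "A"
NEGATIVE = "N"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


def confusion(y_true, y_pred, positive: str = POSITIVE) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) as fractions in [0, 1]."""
    total = cm.p + cm.n
    if total == 0:
        raise EvaluationError("all-zero confusion matrix")
    accuracy = (cm.tp + cm.tn) / total
    if cm.p == 0:
        warnings.warn("sensitivity undefined (no positive examples); reporting NaN")
        sensitivity = float("nan")
    else:
        sensitivity = cm.tp / cm.p
    if cm.n == 0:
        warnings.warn("specificity undefined (no negative examples); reporting NaN")
        specificity = float("nan")
    else:
        specificity = cm.tn / cm.n
    return accuracy, sensitivity, specificity


@dataclass
class FoldResult:
    fold_id: str
    cm: ConfusionMatrix
    accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float


@dataclass
class EvalReport:
    scheme: str  # {kfold, losocv, stage_stratified}
    per_fold: list[FoldResult]
    aggregate: dict[str, float]
    config_fingerprint: str
    notes: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, FoldResult):
                return {
                    "fold": o.fold_id,
                    "cm": {"tp": o.cm.tp, "fp": o.cm.fp, "fn": o.cm.fn, "tn": o.cm.tn},
                    "accuracy_pct": o.accuracy_pct,
                    "sensitivity_pct": o.sensitivity_pct,
                    "specificity_pct": o.specificity_pct,
                }
            raise TypeError(type(o))

        return json.dumps(
            {
                "scheme": self.scheme,
                "per_fold": self.per_fold,
                "aggregate": self.aggregate,
                "config_fingerprint": self.config_fingerprint,
                "notes": self.notes,
            },
            default=enc,
            sort_keys=True,
            indent=2,
            allow_nan=True,
        )


def _fingerprint(X, y, spec: ClassifierSpec, extra: dict) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(",".join(map(str, y)).encode())
    h.update(
        json.dumps(
            [spec.family, spec.hyperparams, spec.seed, extra], sort_keys=True
        ).encode()
    )
    return h.hexdigest()[:16]


def _fold_result(fold_id, y_true, y_pred) -> FoldResult:
    cm = confusion(y_true, y_pred)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        acc, sens, spec_ = metrics(cm)
    return FoldResult(
        fold_id=str(fold_id),
        cm=cm,
        accuracy_pct=100 * acc,
        sensitivity_pct=100 * sens,
        specificity_pct=100 * spec_,
    )


def _aggregate(folds: list[FoldResult]) -> dict[str, float]:
    """Unweighted fold means (NaN-aware) plus pooled-confusion metrics."""
    out: dict[str, float] = {}
    for name in ("accuracy_pct", "sensitivity_pct", "specificity_pct"):
        vals = np.array([getattr(f, name) for f in folds], dtype=float)
        defined = vals[~np.isnan(vals)]
        out[f"mean_{name}"] = float(defined.mean()) if len(defined) else float("nan")
        out[f"n_folds_defined_{name}"] = int(len(defined))
        out[f"mean_{name}_nan_as_zero"] = float(np.nan_to_num(vals).mean())
    pooled = ConfusionMatrix(0, 0, 0, 0)
    for f in folds:
        pooled = pooled + f.cm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        acc, sens, spec_ = metrics(pooled)
    out["pooled_accuracy_pct"] = 100 * acc
    out["pooled_sensitivity_pct"] = 100 * sens
    out["pooled_specificity_pct"] = 100 * spec_
    return out


def kfold_cv(
    features,
    spec: ClassifierSpec,
    k: int = 5,
    seed: int = 0,
    labels=None,
) -> EvalReport:
    """Stratified k-fold CV at the window/spectrogram level."""
    from .classifiers import _as_xy

    X, y = _as_xy(features, labels)
    if len(X) < k:
        raise EvaluationError(f"k={k} > n={len(X)}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise EvaluationError("both classes must be present")
    if counts.min() < k:
        raise EvaluationError(
            f"k={k} exceeds minority class count {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for i, (tr, te) in enumerate(skf.split(X, y)):
        model = train(X[tr], spec, labels=y[tr])
        folds.append(_fold_result(i, y[te], np.asarray(predict(model, X[te]))))
    return EvalReport(
        scheme="kfold",
        per_fold=folds,
        aggregate=_aggregate(folds),
        config_fingerprint=_fingerprint(X, y, spec, {"scheme": "kfold", "k": k, "seed": seed}),
    )


def losocv(features, spec: ClassifierSpec, groups=None, labels=None) -> EvalReport:
    """Leave-one-subject-out CV: one fold per subject id."""
    from .bof import BofVector, feature_matrix
    from .classifiers import _as_xy

    if groups is None:
        if not (len(features) and isinstance(features[0], BofVector)):
            raise EvaluationError("groups (subject ids) required for losocv")
        X, y, groups, _ = feature_matrix(features)
    else:
        X, y = _as_xy(features, labels)
        groups = np.asarray(groups)
    subjects = sorted(set(groups))
    if len(subjects) < 2:
        raise EvaluationError("losocv needs >= 2 subjects")
    folds = []
    for subj in subjects:
        te = groups == subj
        tr = ~te
        if len(np.unique(y[tr])) < 2:
            raise EvaluationError(
                f"training split for held-out subject {subj} is single-class"
            )
        model = train(X[tr], spec, labels=y[tr])
        folds.append(_fold_result(subj, y[te], np.asarray(predict(model, X[te]))))
    return EvalReport(
        scheme="losocv",
        per_fold=folds,
        aggregate=_aggregate(folds),
        config_fingerprint=_fingerprint(X, y, spec, {"scheme": "losocv"}),
        notes={
            "nan_convention": "undefined per-subject metrics excluded from the mean; "
            "mean_*_nan_as_zero reports the include-as-zero variant",
        },
    )


def stage_stratified_eval(
    features,
    spec: ClassifierSpec,
    stages=None,
    balance: str = "none",
    seed: int = 0,
    k: int = 5,
    labels=None,
) -> dict[str, EvalReport]:
    """Independent k-fold evaluation inside the REM and NREM strata.

    ``balance="random_undersample"`` subsamples the majority class down to
    the minority count with the given seed before evaluation; on an
    already-balanced stratum it is a no-op.
    """
    from .bof import BofVector, feature_matrix
    from .classifiers import _as_xy

    if stages is None:
        if not (len(features) and isinstance(features[0], BofVector)):
            raise EvaluationError("stages required for stage-stratified evaluation")
        X, y, _, stages = feature_matrix(features)
    else:
        X, y = _as_xy(features, labels)
        stages = np.asarray(stages)
    if balance not in ("none", "random_undersample"):
        raise ValueError(f"unknown balance mode {balance!r}")
    known = set(stages) & {"REM", "NREM"}
    if not known:
        raise EvaluationError(
            "no REM/NREM stage labels present; stage-stratified evaluation refused"
        )
    rng = np.random.default_rng(seed)
    out: dict[str, EvalReport] = {}
    for stage in ("REM", "NREM"):
        m = stages == stage
        if not m.any():
            continue
        Xs, ys = X[m], y[m]
        if len(np.unique(ys)) < 2:
            raise EvaluationError(f"stratum {stage} contains a single class")
        if balance == "random_undersample":
            idx = balanced_indices(ys, rng)
            Xs, ys = Xs[idx], ys[idx]
        report = kfold_cv(Xs, spec, k=k, seed=seed, labels=ys)
        report.scheme = "stage_stratified"
        report.notes["stage"] = stage
        report.notes["balance"] = balance
        out[stage] = report
    return out


def balanced_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices after undersampling the majority class to the minority count.

    Already-balanced input returns all indices (sorted), i.e. a no-op.
    """
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep = []
    for c, n in zip(classes, counts):
        idx = np.flatnonzero(y == c)
        if n > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))
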