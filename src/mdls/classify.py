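"""Classifier training and evaluation for the three-size experiment.

Three model families are supported — logistic regression, random forest and
a linear support vector machine (default operating point: linear kernel,
one-vs-rest decision function, C = 100, gamma = 1e-4, probability estimates
on; gamma is inert for a linear kernel and is stored only for fidelity).

Evaluation tallies its own confusion matrix (rows = actual, columns =
predicted) and derives per-class one-vs-rest counts TP/TN/FP/FN, from which
accuracy, precision, recall and F1 are computed:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 TP / (2 TP + FP + FN)

Headline precision/recall/F1 are support-weighted averages of the per-class
values (macro averages are also reported); the headline accuracy is the
multi-class trace / n, reported alongside the mean per-class one-vs-rest
accuracy, which differs in the multi-class case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("lr", "rf", "svm")

SVM_DEFAULTS: Mapping[str, object] = {
    "kernel": "linear",
    "decision_function_shape": "ovr",
    "C": 100.0,
    "gamma": 0.0001,
    "probability": True,
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A model family plus hyperparameters and a seed."""

    model: str = "svm"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODEL_FAMILIES:
            raise ValueError(f"model must be one of {MODEL_FAMILIES}, got {self.model!r}")
        c = self.hyperparameters.get("C")
        if c is not None and float(c) <= 0:
            raise ValueError("C must be positive")


def build_estimator(spec: ClassifierSpec):
    """Unfitted scikit-learn estimator for a spec.

    SVM and LR are wrapped in a standardization pipeline (the log-scale
    descriptors have heterogeneous variances); the random forest is
    scale-invariant and used bare.
    """
    if spec.model == "svm":
        params = dict(SVM_DEFAULTS)
        params.update(spec.hyperparameters)
        if params.get("kernel") == "linear" and "gamma" in params:
            logger.info(
                "SVM gamma=%s stored but inert for a linear kernel", params["gamma"]
            )
        clf = SVC(random_state=spec.seed, **params)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    if spec.model == "lr":
        params = {"C": 1.0, "max_iter": 5000}
        params.update(spec.hyperparameters)
        clf = LogisticRegression(random_state=spec.seed, **params)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    params = {"n_estimators": 100}
    params.update(spec.hyperparameters)
    return RandomForestClassifier(random_state=spec.seed, **params)


def without_probability(estimator):
    """Clone an estimator with probability estimates disabled when supported.

    Feature-count sweeps and elimination rankings only need hard predictions,
    and SVM probability calibration costs an internal cross-validation per
    fit, so sweep code paths use this variant.
    """
    from sklearn.base import clone

    est = clone(estimator)
    if "probability" in est.get_params():
        est.set_params(probability=False)
    return est


def split_train_test(
    X: np.ndarray, y: np.ndarray, ratio: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/test partition (default 7:3), deterministic per seed."""
    y = np.asarray(y)
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members to stratify")
    return train_test_split(
        np.asarray(X), y, train_size=ratio, stratify=y, random_state=seed
    )


def train_classifier(spec: ClassifierSpec, X_train: np.ndarray, y_train: np.ndarray):
    """Fit the spec's model; refuses single-class training data."""
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data contains a single class")
    est = build_estimator(spec)
    est.fit(np.asarray(X_train, dtype=float), y_train)
    return est


@dataclass
class EvaluationReport:
    """Confusion matrix plus the derived one-vs-rest metrics."""

    confusion: np.ndarray  # (n_classes, n_classes), rows = actual
    classes: np.ndarray
    accuracy: float
    precision: float  # support-weighted
    recall: float
    f1: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    per_class: dict  # label -> {tp, tn, fp, fn, accuracy, precision, recall, f1}
    accuracy_ovr_mean: float

    @property
    def per_class_recall(self) -> np.ndarray:
        return np.array([self.per_class[c]["recall"] for c in self.classes])

    def to_dict(self) -> dict:
        return {
            "classes": [int(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "accuracy_ovr_mean": self.accuracy_ovr_mean,
            "per_class": {
                str(k): {kk: float(vv) for kk, vv in v.items()}
                for k, v in self.per_class.items()
            },
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def report_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray | None = None
) -> EvaluationReport:
    """Build the evaluation report by direct tallying of the prediction list."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty test set")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    if not (np.isin(y_true, classes).all() and np.isin(y_pred, classes).all()):
        raise ValueError("labels outside the declared class set")

    idx = {c: i for i, c in enumerate(classes)}
    K, n = len(classes), len(y_true)
    conf = np.zeros((K, K), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[idx[t], idx[p]] += 1

    per_class = {}
    supports = conf.sum(axis=1)
    for i, c in enumerate(classes):
        tp = int(conf[i, i])
        fn = int(supports[i] - tp)
        fp = int(conf[:, i].sum() - tp)
        tn = int(n - tp - fn - fp)
        per_class[c] = {
            "tp": tp,
            "tn": tn,
            "fp": fp,
            "fn": fn,
            "accuracy": _safe_div(tp + tn, n),
            "precision": _safe_div(tp, tp + fp),
            "recall": _safe_div(tp, tp + fn),
            "f1": _safe_div(2 * tp, 2 * tp + fp + fn),
        }

    weights = supports / n
    prec = np.array([per_class[c]["precision"] for c in classes])
    rec = np.array([per_class[c]["recall"] for c in classes])
    f1 = np.array([per_class[c]["f1"] for c in classes])
    acc_ovr = np.array([per_class[c]["accuracy"] for c in classes])
    return EvaluationReport(
        confusion=conf,
        classes=classes,
        accuracy=float(np.trace(conf) / n),
        precision=float(weights @ prec),
        recall=float(weights @ rec),
        f1=float(weights @ f1),
        precision_macro=float(prec.mean()),
        recall_macro=float(rec.mean()),
        f1_macro=float(f1.mean()),
        per_class=per_class,
        accuracy_ovr_mean=float(acc_ovr.mean()),
    )


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray) -> EvaluationReport:
    """Predict on the held-out set and tally the evaluation report."""
    X_test = np.asarray(X_test, dtype=float)
    if X_test.shape[0] == 0:
        raise ValueError("empty test set")
    y_pred = model.predict(X_test)
    return report_from_predictions(np.asarray(y_test), y_pred)


def cross_validate(
    spec_or_estimator, X: np.ndarray, y: np.ndarray, folds: int = 5, seed: int = 0
) -> tuple[float, float, np.ndarray]:
    """Stratified k-fold accuracy: (mean, sd, per-fold scores)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if len(y) < folds:
        raise ValueError("fewer samples than folds")
    if isinstance(spec_or_estimator, ClassifierSpec):
        template = build_estimator(spec_or_estimator)
    else:
        template = spec_or_estimator
    from sklearn.base import clone

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        model = clone(template)
        model.fit(X[tr], y[tr])
        scores.append(float(np.mean(model.predict(X[te]) == y[te])))
    scores = np.asarray(scores)
    sd = float(scores.std(ddof=1)) if len(scores) > 1 else 0.0
    return float(scores.mean()), sd, scores
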