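"""The eight-classifier panel, stratified cross-validation, and the metric table.

The classifier families mirror the consensus panel used throughout the
pipeline: a small feed-forward network (``DL``), AdaBoost (``ada``),
Bernoulli naive Bayes (``bnb``), k-nearest neighbors (``kNN``), logistic
regression (``lreg``), random forest (``rf``), support vector classification
(``svc``), and gradient-boosted trees (``xgb``).  All are trained on binary
fingerprint matrices and evaluated with an eight-metric table
(AUC, F1, precision, recall, accuracy, specificity, Cohen's kappa, MCC).

Evaluation uses stratified fivefold cross-validation with out-of-fold scores
pooled before the metric table is computed; the deep-learning family is also
evaluable on a stratified 20% holdout, matching the common practice of giving
neural models a fixed external test set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

ALGORITHM_NAMES = ("DL", "ada", "bnb", "kNN", "lreg", "rf", "svc", "xgb")


class StratificationError(ValueError):
    """A class has too few members for the requested number of folds."""


@dataclass(frozen=True)
class AlgorithmSpec:
    """One member of the eight-algorithm panel with its hyperparameters."""

    name: str
    hyperparameters: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ALGORITHM_NAMES:
            raise ValueError(
                f"unknown algorithm {self.name!r}; expected one of {ALGORITHM_NAMES}"
            )

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)


def default_panel(seed: int = 0) -> list[AlgorithmSpec]:
    """The full eight-member panel with library-default hyperparameters."""
    return [AlgorithmSpec(name, seed=seed) for name in ALGORITHM_NAMES]


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of_record: np.ndarray
    seed: int

    def indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.fold_of_record == fold)
        train = np.flatnonzero(self.fold_of_record != fold)
        return train, test


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricTable:
    auc: float
    f1: float
    precision: float
    recall: float
    accuracy: float
    specificity: float
    kappa: float
    mcc: float

    def to_row(self) -> dict:
        return {
            "AUC": self.auc,
            "F1": self.f1,
            "Precision": self.precision,
            "Recall": self.recall,
            "Accuracy": self.accuracy,
            "Specificity": self.specificity,
            "Cohen's kappa": self.kappa,
            "MCC": self.mcc,
        }


@dataclass
class CVResult:
    algorithm: AlgorithmSpec
    assignment: FoldAssignment
    out_of_fold_scores: np.ndarray
    pooled_confusion: ConfusionMatrix
    metrics: MetricTable


def stratified_folds(labels: Sequence[int], k: int, seed: int) -> FoldAssignment:
    """Assign records to k folds preserving the class ratio.

    Per-fold class counts differ from perfect stratification by at most one.
    Deterministic for a fixed seed.
    """
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("both classes must be present")
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of_record = np.empty(len(y), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        fold_of_record[test_idx] = fold
    return FoldAssignment(k, fold_of_record, seed)


class _SigmoidMarginModel:
    """Wraps a margin-only classifier, mapping its decision value to [0, 1].

    A logistic link on the decision function keeps scores comparable with the
    probability-producing panel members; it preserves the ranking (and hence
    the AUC) of the raw margins.
    """

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        self.estimator.fit(X, y)
        return self

    def predict_proba_positive(self, X) -> np.ndarray:
        margin = self.estimator.decision_function(X)
        return 1.0 / (1.0 + np.exp(-margin))


class _ProbaModel:
    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        self.estimator.fit(X, y)
        return self

    def predict_proba_positive(self, X) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        positive_col = list(self.estimator.classes_).index(1)
        return proba[:, positive_col]


def _build_estimator(spec: AlgorithmSpec):
    p = spec.params
    seed = spec.seed
    if spec.name == "DL":
        # small feed-forward net: two rectified hidden layers, sigmoid output
        defaults = dict(
            hidden_layer_sizes=(64, 32),
            activation="relu",
            max_iter=500,
            random_state=seed,
        )
        return _ProbaModel(MLPClassifier(**{**defaults, **p}))
    if spec.name == "ada":
        return _ProbaModel(AdaBoostClassifier(random_state=seed, **p))
    if spec.name == "bnb":
        return _ProbaModel(BernoulliNB(**p))
    if spec.name == "kNN":
        return _ProbaModel(KNeighborsClassifier(**p))
    if spec.name == "lreg":
        return _ProbaModel(LogisticRegression(max_iter=1000, random_state=seed, **p))
    if spec.name == "rf":
        return _ProbaModel(RandomForestClassifier(random_state=seed, **p))
    if spec.name == "svc":
        return _SigmoidMarginModel(SVC(random_state=seed, **p))
    if spec.name == "xgb":
        return _ProbaModel(
            XGBClassifier(random_state=seed, eval_metric="logloss", **p)
        )
    raise ValueError(spec.name)  # unreachable; __post_init__ validates


@dataclass
class TrainedModel:
    """Opaque handle: a fitted estimator plus the feature width it expects."""

    spec: AlgorithmSpec
    _model: object
    n_features: int


def train_classifier(spec: AlgorithmSpec, X: np.ndarray, y: np.ndarray) -> TrainedModel:
    """Fit one panel member; training is seeded and repeatable."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise ValueError("X rows must match y length")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes")
    model = _build_estimator(spec).fit(X, y)
    return TrainedModel(spec, model, X.shape[1])


def predict_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Probability-like score in [0, 1] per row; higher = more likely active."""
    X = np.asarray(X, dtype=np.float64)
    if X.size == 0:
        return np.zeros(0)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1]} does not match training width {model.n_features}"
        )
    scores = model._model.predict_proba_positive(X)
    return np.clip(scores, 0.0, 1.0)


def confusion_matrix(
    y: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> ConfusionMatrix:
    """Tally the 2×2 confusion table with the ≥-threshold labeling rule."""
    y = np.asarray(y)
    scores = np.asarray(scores)
    if len(y) != len(scores):
        raise ValueError("y and scores must have equal length")
    pred = scores >= threshold
    tp = int(np.sum((y == 1) & pred))
    fp = int(np.sum((y == 0) & pred))
    fn = int(np.sum((y == 1) & ~pred))
    tn = int(np.sum((y == 0) & ~pred))
    return ConfusionMatrix(tp, fp, fn, tn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def compute_metrics(
    cm: ConfusionMatrix, y: Sequence[int], scores: Sequence[float]
) -> MetricTable:
    """Eight-metric table from a confusion matrix plus ranking scores.

    Threshold metrics come from the closed forms on (tp, fp, fn, tn); AUC is
    the area under the ROC curve of the continuous scores.  Metrics whose
    denominator vanishes (precision/F1 with no predicted positives, MCC with
    an empty margin) are defined as 0.
    """
    y = np.asarray(y)
    if cm.n != len(y):
        raise ValueError("confusion matrix total must equal number of labels")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: only one class present")
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    n = cm.n
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    accuracy = _safe_div(tp + tn, n)
    specificity = _safe_div(tn, tn + fp)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    # Cohen's kappa: observed vs chance agreement
    p_obs = accuracy
    p_chance = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    kappa = _safe_div(p_obs - p_chance, 1.0 - p_chance)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    auc = float(roc_auc_score(y, np.asarray(scores)))
    return MetricTable(auc, f1, precision, recall, accuracy, specificity, kappa, mcc)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: AlgorithmSpec,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVResult:
    """Stratified k-fold cross-validation with pooled out-of-fold scoring.

    Each record is scored exactly once, by the model trained without its
    fold; the pooled scores yield one confusion matrix and one metric table.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    assignment = stratified_folds(y, k, seed)
    oof = np.full(len(y), np.nan)
    for fold in range(k):
        train_idx, test_idx = assignment.indices(fold)
        model = train_classifier(spec, X[train_idx], y[train_idx])
        oof[test_idx] = predict_scores(model, X[test_idx])
    assert not np.isnan(oof).any()
    cm = confusion_matrix(y, oof, threshold)
    return CVResult(spec, assignment, oof, cm, compute_metrics(cm, y, oof))


def holdout_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    spec: AlgorithmSpec,
    fraction: float = 0.2,
    seed: int = 0,
    threshold: float = 0.5,
    return_split: bool = False,
) -> MetricTable:
    """Stratified holdout evaluation (default: a 20% external test set).

    The holdout size is ceil(fraction × n); the model is trained on the
    remainder and the metric table computed on the held-out part only.
    With ``return_split`` the (train, test) index arrays are returned
    alongside the metrics for reproducibility audits.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n_test = math.ceil(fraction * len(y))
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), test_size=n_test, stratify=y, random_state=seed
    )
    model = train_classifier(spec, X[idx_train], y[idx_train])
    scores = predict_scores(model, X[idx_test])
    cm = confusion_matrix(y[idx_test], scores, threshold)
    metrics = compute_metrics(cm, y[idx_test], scores)
    if return_split:
        return metrics, (idx_train, idx_test)
    return metrics


def metric_report(results: Mapping[str, MetricTable]):
    """Stack per-algorithm metric tables into one DataFrame, panel order."""
    import pandas as pd

    rows = []
    for name in ALGORITHM_NAMES:
        if name in results:
            rows.append({"Method": name} | results[name].to_row())
    for name in results:
        if name not in ALGORITHM_NAMES:
            rows.append({"Method": name} | results[name].to_row())
    return pd.DataFrame(rows)
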