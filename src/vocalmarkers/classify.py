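"""Classifier families, confusion-matrix metrics, and cross-validated ROC.

Five classifier families are wrapped with the hyperparameters of the
screening study as defaults: an RBF-kernel SVM (gamma 0.1, moderate
penalty C=1), gradient boosting (max depth 6, learning rate 0.1), an
entropy decision tree (depth 8, 23 leaves, min split 2), a random forest
(40 trees, 4 random features per split), and distance-weighted kNN
(k=10, Manhattan metric, leaf size 20).

Binary metrics treat class 1 (pathological) as positive:

    Acc  = (TP+TN)/(TP+TN+FP+FN)        Sens = TP/(TP+FN)
    Spec = TN/(TN+FP)                   Prec = TP/(TP+FP)
    F1   = 2*Prec*Sens/(Prec+Sens)
    MCC  = (TP*TN-FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Multiclass metrics are unweighted (macro) one-vs-rest averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .errors import (
    DegenerateTrainingError,
    ParameterError,
    StratificationError,
)
from .features import FEATURE_NAMES

FAMILIES = ("svm", "gboost", "dtree", "rforest", "knn")


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus hyperparameter overrides."""

    family: str = "svm"
    hyperparameters: dict = field(default_factory=dict)
    grid: dict | None = None  # optional exhaustive grid search space

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown classifier family {self.family!r}")


@dataclass
class ConfusionMatrix:
    """Count matrix; ``matrix[i, j]`` = true class ``labels[i]`` predicted ``labels[j]``."""

    matrix: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ParameterError("confusion matrix must be square")
        if np.any(self.matrix < 0):
            raise ParameterError("counts must be non-negative")
        if self.matrix.sum() == 0:
            raise ParameterError("confusion matrix is empty")

    @classmethod
    def from_binary_counts(cls, tp: int, tn: int, fp: int, fn: int) -> "ConfusionMatrix":
        return cls(matrix=np.array([[tn, fp], [fn, tp]]), labels=(0, 1))

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels=None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if labels is None:
            labels = tuple(sorted(set(y_true) | set(y_pred)))
        index = {lbl: i for i, lbl in enumerate(labels)}
        m = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            m[index[t], index[p]] += 1
        return cls(matrix=m, labels=tuple(labels))

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def is_binary(self) -> bool:
        return self.matrix.shape[0] == 2

    def binary_counts(self, positive=1) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) treating ``positive`` as the positive class."""
        i = self.labels.index(positive)
        tp = int(self.matrix[i, i])
        fn = int(self.matrix[i].sum() - tp)
        fp = int(self.matrix[:, i].sum() - tp)
        tn = int(self.total - tp - fn - fp)
        return tp, tn, fp, fn


@dataclass(frozen=True)
class MetricsSet:
    acc: float
    sens: float
    spec: float
    prec: float
    f1: float
    mcc: float
    auc: float = float("nan")
    mcc_defined: bool = True

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Half-up rounding for comparison against printed result tables."""
        out = {}
        for name in ("acc", "sens", "spec", "prec", "f1", "mcc", "auc"):
            value = getattr(self, name)
            if np.isnan(value):
                out[name] = value
            else:
                q = Decimal(1).scaleb(-ndigits)
                out[name] = float(Decimal(repr(value)).quantize(q, ROUND_HALF_UP))
        return out


def _binary_metrics(tp: int, tn: int, fp: int, fn: int) -> MetricsSet:
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    factors = [tp + fp, tp + fn, tn + fp, tn + fn]
    if all(f > 0 for f in factors):
        mcc = (tp * tn - fp * fn) / np.sqrt(np.prod([float(f) for f in factors]))
        defined = True
    else:
        mcc, defined = 0.0, False
    return MetricsSet(
        acc=acc, sens=sens, spec=spec, prec=prec, f1=f1,
        mcc=float(mcc), mcc_defined=defined,
    )


def compute_metrics(cm: ConfusionMatrix, positive=1) -> MetricsSet:
    """Metrics of a confusion matrix: binary as printed, multiclass macro OvR."""
    if cm.is_binary:
        return _binary_metrics(*cm.binary_counts(positive))
    per_class = [_binary_metrics(*cm.binary_counts(lbl)) for lbl in cm.labels]
    return MetricsSet(
        acc=float(np.trace(cm.matrix)) / cm.total,  # overall agreement
        sens=float(np.mean([m.sens for m in per_class])),
        spec=float(np.mean([m.spec for m in per_class])),
        prec=float(np.mean([m.prec for m in per_class])),
        f1=float(np.mean([m.f1 for m in per_class])),
        mcc=float(np.mean([m.mcc for m in per_class])),
        mcc_defined=all(m.mcc_defined for m in per_class),
    )


def _build_estimator(spec: ClassifierSpec, seed: int, n_features: int):
    hp = dict(spec.hyperparameters)
    if spec.family == "svm":
        defaults = dict(C=1.0, kernel="rbf", gamma=0.1, probability=True,
                        random_state=seed)
        defaults.update(hp)
        return SVC(**defaults)
    if spec.family == "gboost":
        defaults = dict(max_depth=6, learning_rate=0.1, n_estimators=100,
                        eval_metric="logloss", random_state=seed)
        defaults.update(hp)
        return XGBClassifier(**defaults)
    if spec.family == "dtree":
        defaults = dict(criterion="entropy", max_depth=8, max_leaf_nodes=23,
                        min_samples_split=2, random_state=seed)
        defaults.update(hp)
        return DecisionTreeClassifier(**defaults)
    if spec.family == "rforest":
        defaults = dict(n_estimators=40, max_features=min(4, n_features),
                        random_state=seed)
        defaults.update(hp)
        return RandomForestClassifier(**defaults)
    defaults = dict(n_neighbors=10, metric="manhattan", weights="distance",
                    leaf_size=20)
    defaults.update(hp)
    return KNeighborsClassifier(**defaults)


@dataclass
class FittedModel:
    """A trained classifier with a uniform scoring interface."""

    estimator: object
    classes: np.ndarray
    feature_names: tuple[str, ...]

    def predict(self, X) -> np.ndarray:
        # estimators are always trained on labels encoded as 0..K-1
        raw = np.asarray(self.estimator.predict(np.asarray(X, dtype=float)))
        return self.classes[raw.astype(int)]

    def predict_score(self, X) -> np.ndarray:
        """Ranking score: P(class 1) for binary, class-probability matrix otherwise."""
        X = np.asarray(X, dtype=float)
        if hasattr(self.estimator, "predict_proba"):
            proba = self.estimator.predict_proba(X)
            return proba[:, 1] if proba.shape[1] == 2 else proba
        scores = self.estimator.decision_function(X)
        return scores

    def predict_margin(self, X) -> np.ndarray:
        """Pre-threshold decision score (used for explanations)."""
        X = np.asarray(X, dtype=float)
        if hasattr(self.estimator, "decision_function"):
            return np.asarray(self.estimator.decision_function(X), dtype=float)
        proba = self.estimator.predict_proba(X)
        p1 = proba[:, 1] if proba.shape[1] == 2 else proba.max(axis=1)
        p1 = np.clip(p1, 1e-12, 1 - 1e-12)
        return np.log(p1 / (1 - p1))


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """(X, y, feature names) from a feature table with a class_label column."""
    names = tuple(c for c in FEATURE_NAMES if c in table.columns)
    if not names:
        names = tuple(
            c for c in table.columns
            if c not in ("record_id", "subject_id", "content", "class_label", "augmented")
        )
    X = table[list(names)].to_numpy(dtype=float)
    y = table["class_label"].to_numpy()
    return X, y, names


def fit_classifier(
    spec: ClassifierSpec,
    train: pd.DataFrame,
    seed: int = 0,
) -> FittedModel:
    """Train one classifier family on a feature table.

    With ``spec.grid`` set, an exhaustive grid search (5-fold CV mean
    accuracy) selects the hyperparameters first.
    """
    X, y, names = feature_matrix(train)
    if np.isnan(X).any():
        raise ParameterError(
            "training features contain missing values; run preprocess first"
        )
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateTrainingError("training set has a single class")

    # xgboost requires labels 0..K-1; map and remember
    y_enc = np.searchsorted(classes, y)
    est = _build_estimator(spec, seed, X.shape[1])
    if spec.grid:
        search = GridSearchCV(est, spec.grid, scoring="accuracy", cv=5)
        search.fit(X, y_enc)
        est = search.best_estimator_
    else:
        est.fit(X, y_enc)
    est._vm_encoded = True
    return FittedModel(estimator=est, classes=classes, feature_names=names)


def _check_stratifiable(y: np.ndarray, k: int) -> None:
    if k < 2:
        raise ParameterError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {counts.min()} rows; cannot stratify into {k} folds"
        )


def cross_validate(
    spec: ClassifierSpec,
    table: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
) -> tuple[MetricsSet, list[MetricsSet], ConfusionMatrix]:
    """Stratified k-fold CV; pooled (micro) metrics over out-of-fold predictions.

    Returns (pooled metrics, per-fold metrics, pooled confusion matrix).
    """
    X, y, _ = feature_matrix(table)
    if np.isnan(X).any():
        raise ParameterError("features contain missing values; run preprocess first")
    _check_stratifiable(y, k)
    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof_pred = np.empty_like(y)
    fold_metrics = []
    for train_idx, test_idx in skf.split(X, y):
        sub = table.iloc[train_idx]
        model = fit_classifier(spec, sub, seed=seed)
        pred = model.predict(X[test_idx])
        oof_pred[test_idx] = pred
        cm_fold = ConfusionMatrix.from_predictions(
            y[test_idx], pred, labels=tuple(classes)
        )
        fold_metrics.append(compute_metrics(cm_fold))
    cm = ConfusionMatrix.from_predictions(y, oof_pred, labels=tuple(classes))
    return compute_metrics(cm), fold_metrics, cm


def roc_points(y_true, scores, positive=1) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by threshold sweep plus trapezoidal AUC; ties give the diagonal."""
    y_bin = (np.asarray(y_true) == positive).astype(int)
    fpr, tpr, _ = roc_curve(y_bin, np.asarray(scores, dtype=float))
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def roc_auc_cv(
    spec: ClassifierSpec,
    table: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
) -> dict:
    """Per-fold ROC curves and AUC via stratified k-fold CV.

    Binary tasks use P(class 1); multiclass tasks average one-vs-rest
    AUCs per fold.  Returns ``{"folds": [...], "mean_auc": m, "sd_auc": s}``.
    """
    X, y, _ = feature_matrix(table)
    if np.isnan(X).any():
        raise ParameterError("features contain missing values; run preprocess first")
    _check_stratifiable(y, k)
    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    aucs = []
    for train_idx, test_idx in skf.split(X, y):
        model = fit_classifier(spec, table.iloc[train_idx], seed=seed)
        scores = model.predict_score(X[test_idx])
        if classes.size == 2:
            fpr, tpr, auc = roc_points(y[test_idx], scores, positive=classes[1])
            folds.append({"fpr": fpr, "tpr": tpr, "auc": auc})
            aucs.append(auc)
        else:
            per_class = []
            curves = {}
            for j, lbl in enumerate(classes):
                fpr, tpr, auc = roc_points(
                    (y[test_idx] == lbl).astype(int), scores[:, j], positive=1
                )
                per_class.append(auc)
                curves[lbl] = {"fpr": fpr, "tpr": tpr, "auc": auc}
            auc = float(np.mean(per_class))
            folds.append({"per_class": curves, "auc": auc})
            aucs.append(auc)
    return {
        "folds": folds,
        "mean_auc": float(np.mean(aucs)),
        "sd_auc": float(np.std(aucs)),
    }
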