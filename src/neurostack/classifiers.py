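"""Uniform classifier abstraction and evaluation metrics.

Seven classical model families sit behind a single spec object: Bernoulli
naive Bayes, RBF-kernel SVM, k-NN, decision trees and the three tree
ensembles (random forest, AdaBoost, gradient boosting). The underlying
learners come from scikit-learn; the abstraction pins the seed and
hyperparameters for provenance. Multiclass precision / recall (sensitivity)
/ specificity / F1 are macro-averaged over one-vs-rest reductions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Any, Mapping, Sequence

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datamodel import ConfigurationError, register_artifact
from .evo_core import ContractError

FAMILIES = (
    "bernoulli_nb",
    "svm_rbf",
    "knn",
    "decision_tree",
    "random_forest",
    "adaboost",
    "gradient_boosting",
)

_ALLOWED_PARAMS: dict[str, set[str]] = {
    "bernoulli_nb": {"alpha", "class_prior", "binarize"},
    "svm_rbf": {"C", "gamma", "class_weight"},
    "knn": {"n_neighbors", "metric", "weights"},
    "decision_tree": {"splitter", "criterion", "max_depth", "min_samples_split", "min_samples_leaf"},
    "random_forest": {"n_estimators", "max_depth", "min_samples_split", "min_samples_leaf"},
    "adaboost": {"n_estimators", "learning_rate"},
    "gradient_boosting": {"n_estimators", "learning_rate", "subsample", "loss", "max_depth"},
}


@dataclass(frozen=True)
class ClassifierSpec:
    family: str = "svm_rbf"
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown classifier family {self.family!r}")
        bad = set(self.hyperparameters) - _ALLOWED_PARAMS[self.family]
        if bad:
            raise ConfigurationError(f"hyperparameters not valid for {self.family}: {sorted(bad)}")
        hp = self.hyperparameters
        gamma = hp.get("gamma", "scale")
        if (
            hp.get("C", 1) <= 0
            or (isinstance(gamma, (int, float)) and gamma <= 0)
            or hp.get("n_neighbors", 1) < 1
        ):
            raise ConfigurationError("C > 0, gamma > 0, k >= 1 required")
        object.__setattr__(self, "hyperparameters", dict(hp))

    def with_params(self, **kw: Any) -> "ClassifierSpec":
        return ClassifierSpec(self.family, {**self.hyperparameters, **kw}, self.seed)


def make_classifier(spec: ClassifierSpec):
    """Instantiate the underlying learner with the spec's seed pinned."""
    hp = dict(spec.hyperparameters)
    if spec.family == "bernoulli_nb":
        return BernoulliNB(**hp)
    if spec.family == "svm_rbf":
        return SVC(kernel="rbf", random_state=spec.seed, **hp)
    if spec.family == "knn":
        return KNeighborsClassifier(**hp)
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.family == "adaboost":
        return AdaBoostClassifier(random_state=spec.seed, **hp)
    if spec.family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=spec.seed, **hp)
    raise ConfigurationError(spec.family)


def fit_predict(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Fit on the training split, return (labels, per-class scores or None)."""
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ContractError("training set must contain at least two classes")
    model = make_classifier(spec)
    model.fit(X_train, y_train)
    pred = model.predict(X_test)
    scores = None
    if hasattr(model, "predict_proba"):
        scores = model.predict_proba(X_test)
    elif hasattr(model, "decision_function"):
        # logistic squash of decision scores: per-sample, batch-independent
        d = np.atleast_2d(model.decision_function(X_test).T).T
        scores = 1.0 / (1.0 + np.exp(-d))
    return pred, scores


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    confusion: list[list[int]]
    classes: list[str]
    roc: dict[str, dict] = field(default_factory=dict)

    @property
    def sensitivity(self) -> float:
        return self.recall

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "confusion": self.confusion,
            "classes": self.classes,
            "roc": self.roc,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(**d)


register_artifact("metrics_report")(MetricsReport)


def compute_metrics(
    y_true: Sequence,
    y_pred: Sequence,
    y_score: np.ndarray | None = None,
    classes: Sequence[str] | None = None,
) -> MetricsReport:
    """Accuracy, macro precision/sensitivity/specificity/F1, confusion, ROC.

    One-vs-rest terms for a class absent from ``y_true`` are undefined and
    excluded from the macro mean with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ContractError("y_true and y_pred must have equal length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = list(classes)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    total = cm.sum()
    acc = float(np.trace(cm)) / total if total else 0.0

    precs, recs, specs, f1s = [], [], [], []
    roc: dict[str, dict] = {}
    for i, c in enumerate(classes):
        support = cm[i].sum()
        if support == 0:
            warnings.warn(f"class {c!r} absent from y_true; excluded from macro means", stacklevel=2)
            continue
        tp = cm[i, i]
        fn = support - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn)
        spec = tn / (tn + fp) if tn + fp else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precs.append(prec)
        recs.append(rec)
        specs.append(spec)
        f1s.append(f1)
        if y_score is not None:
            sc = y_score[:, i] if y_score.ndim == 2 else y_score
            fpr, tpr, _ = roc_curve((y_true == c).astype(int), sc)
            roc[c] = {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "auc": float(auc(fpr, tpr))}

    def m(v: list[float]) -> float:
        return float(np.mean(v)) if v else 0.0

    return MetricsReport(acc, m(precs), m(recs), m(specs), m(f1s), cm.tolist(), classes, roc)


def macro_f1(y_true: Sequence, y_pred: Sequence, classes: Sequence[str] | None = None) -> float:
    return compute_metrics(y_true, y_pred, classes=classes).f1


def cv_score(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    metric: str = "accuracy",
    cv_folds: int = 5,
    cv_repeats: int = 1,
    seed: int = 0,
) -> float:
    """Mean held-out metric over repeated stratified K-fold CV.

    Split seeds derive deterministically from ``seed`` + repeat index, so
    the score is a pure function of (spec, data, seed).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < cv_folds:
        raise ContractError(
            f"smallest class has {counts.min()} samples; cannot stratify into {cv_folds} folds"
        )
    scores = []
    for rep in range(cv_repeats):
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed + rep)
        for tr, te in skf.split(X, y):
            pred, _ = fit_predict(spec, X[tr], y[tr], X[te])
            if metric == "accuracy":
                scores.append(float(np.mean(pred == y[te])))
            elif metric == "f1":
                scores.append(macro_f1(y[te], pred, classes=np.unique(y).tolist()))
            else:
                raise ConfigurationError(f"unknown metric {metric!r}")
    return float(np.mean(scores))


def grid_search(
    spec_template: ClassifierSpec,
    grid: Mapping[str, Sequence[Any]],
    X: np.ndarray,
    y: np.ndarray,
    metric: str = "accuracy",
    cv_folds: int = 5,
    cv_repeats: int = 1,
    seed: int = 0,
) -> tuple[ClassifierSpec, float]:
    """Exhaustive grid search under the same CV protocol as wrapper fitness.

    Ties are broken by first-in-grid order.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ContractError("grid must be non-empty")
    keys = list(grid)
    best_spec, best_score = None, -np.inf
    for combo in product(*(grid[k] for k in keys)):
        cand = spec_template.with_params(**dict(zip(keys, combo)))
        s = cv_score(cand, X, y, metric, cv_folds, cv_repeats, seed)
        if s > best_score:
            best_spec, best_score = cand, s
    return best_spec, best_score
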