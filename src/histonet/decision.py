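"""Treatment-response decision support.

Meta-features span very different numeric ranges, so each cross-validation
fold min-max-normalizes the features with statistics fitted on its training
part only.  Classification performance is estimated by stratified k-fold
cross-validation (default ten folds) over a panel of simple classifiers that
tolerate small cohorts: a majority-class "educated guess" reference, Gaussian
Naive Bayes, linear and RBF support-vector machines, logistic regression and
k-nearest-neighbors (the configuration of record is 5-NN with Manhattan
distance).  Two-dimensional Naive-Bayes posterior surfaces are provided for
visualizing decision boundaries in selected feature pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.dummy import DummyClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "ClassifierSpec",
    "CVResult",
    "minmax_scale",
    "stratified_folds",
    "cross_validate",
    "nb_decision_surface",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to cross-validate.

    ``kind`` is one of ``naive_bayes``, ``linear_svm``, ``rbf_svm``,
    ``logistic_regression``, ``knn`` or ``educated_guess`` (majority class).
    ``k``/``metric`` apply to knn only.  Unprinted hyperparameters use the
    conventional defaults (C = 1, gamma = 1/(d * var), L2 with C = 1).
    """

    kind: str = "knn"
    k: int = 5
    metric: str = "manhattan"
    seed: int = 0

    def __post_init__(self) -> None:
        kinds = (
            "naive_bayes",
            "linear_svm",
            "rbf_svm",
            "logistic_regression",
            "knn",
            "educated_guess",
        )
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.metric not in ("euclidean", "manhattan"):
            raise ValueError("metric must be euclidean or manhattan")


@dataclass
class CVResult:
    """Per-fold accuracy / AUC-ROC and their arithmetic means.

    Folds whose test part contains one class have no defined AUC; they are
    recorded as NaN and excluded from ``mean_auc``.
    """

    per_fold: list[tuple[float, float]]
    fold_assignments: np.ndarray
    notes: list[str] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([a for a, _ in self.per_fold]))

    @property
    def mean_auc(self) -> float:
        aucs = [u for _, u in self.per_fold if np.isfinite(u)]
        return float(np.mean(aucs)) if aucs else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_fold, columns=["accuracy", "auc_roc"]).rename_axis(
            "fold"
        )


def minmax_scale(
    train: np.ndarray, apply_to: np.ndarray | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Map each column through (x - min) / (max - min) of the *training* fold.

    Applied values are clipped to [0, 1]; constant training columns map to 0.
    Returns the scaled array and the fitted (min, max) ranges.
    """
    tr = np.asarray(train, dtype=np.float64)
    if tr.ndim != 2 or tr.shape[0] == 0:
        raise ValueError("train must be a non-empty 2-D array")
    lo, hi = tr.min(axis=0), tr.max(axis=0)
    span = hi - lo
    target = tr if apply_to is None else np.asarray(apply_to, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (target - lo) / np.where(span > 0, span, 1.0), 0.0)
    return np.clip(scaled, 0.0, 1.0), (lo, hi)


def stratified_folds(labels: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each sample to one of ``k`` stratified test folds.

    Per-fold class proportions deviate from the global ones by at most one
    sample.  If the rarest class has fewer than ``k`` members the number of
    folds adapts down to it (with a warning) rather than failing.
    """
    y = np.asarray(labels)
    n = len(y)
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of samples ({n})")
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    k_eff = int(min(k, counts.min()))
    if k_eff < k:
        warnings.warn(
            f"rarest class has {counts.min()} members; using {k_eff} folds",
            stacklevel=2,
        )
        k_eff = max(k_eff, 2)
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), y)):
        assignment[test_idx] = fold
    return assignment


def _make_classifier(spec: ClassifierSpec, n_train: int | None = None):
    if spec.kind == "naive_bayes":
        return GaussianNB()
    if spec.kind == "linear_svm":
        return SVC(kernel="linear", C=1.0, random_state=spec.seed)
    if spec.kind == "rbf_svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=spec.seed)
    if spec.kind == "logistic_regression":
        return LogisticRegression(C=1.0, max_iter=1000, random_state=spec.seed)
    if spec.kind == "educated_guess":
        return DummyClassifier(strategy="prior")
    k = spec.k if n_train is None else min(spec.k, n_train)
    return KNeighborsClassifier(n_neighbors=k, metric=spec.metric, weights="uniform")


def _scores(spec: ClassifierSpec, clf, x_train, y_train, x_test) -> np.ndarray:
    """Continuous responder scores for AUC: posterior for NB/LR, decision
    function for SVMs, distance-weighted vote fraction for knn."""
    if spec.kind in ("linear_svm", "rbf_svm"):
        return clf.decision_function(x_test)
    if spec.kind == "knn":
        weighted = KNeighborsClassifier(
            n_neighbors=min(spec.k, len(x_train)),
            metric=spec.metric,
            weights="distance",
        ).fit(x_train, y_train)
        return weighted.predict_proba(x_test)[:, -1]
    return clf.predict_proba(x_test)[:, -1]


def cross_validate(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray | pd.Series,
    spec: ClassifierSpec = ClassifierSpec(),
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation with per-fold min-max scaling.

    Rows are brought into a canonical lexicographic order before the seeded
    fold construction, so the result does not depend on the input row order.
    Returns per-fold (accuracy, AUC-ROC) plus fold assignments in the
    original row order.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("features must be 2-D with one label per row")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    canon = np.lexsort(np.vstack([x.T, np.unique(y, return_inverse=True)[1]]))
    xs, ys = x[canon], y[canon]
    assignment = stratified_folds(ys, k=k, seed=seed)
    per_fold: list[tuple[float, float]] = []
    notes: list[str] = []
    for fold in range(assignment.max() + 1):
        test = assignment == fold
        x_tr, _ = minmax_scale(xs[~test])
        x_te, _ = minmax_scale(xs[~test], xs[test])
        clf = _make_classifier(spec, n_train=int((~test).sum()))
        clf.fit(x_tr, ys[~test])
        acc = accuracy_score(ys[test], clf.predict(x_te))
        if len(np.unique(ys[test])) < 2:
            auc = float("nan")
            notes.append(f"fold {fold}: single-class test part, AUC undefined")
        else:
            scores = _scores(spec, clf, x_tr, ys[~test], x_te)
            auc = float(roc_auc_score(ys[test], scores))
        per_fold.append((float(acc), auc))
    original_assignment = np.empty_like(assignment)
    original_assignment[canon] = assignment
    return CVResult(per_fold=per_fold, fold_assignments=original_assignment, notes=notes)


def nb_decision_surface(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray | pd.Series,
    grid_resolution: int = 100,
    positive: str | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian Naive-Bayes posterior of the responder class on a 2-D grid.

    ``features`` must have exactly two columns (typically already min-max
    scaled); the grid spans each column's range.  Returns (xx, yy, posterior)
    with posterior values in [0, 1].
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("exactly two feature columns required")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    clf = GaussianNB().fit(x, y)
    gx = np.linspace(x[:, 0].min(), x[:, 0].max(), grid_resolution)
    gy = np.linspace(x[:, 1].min(), x[:, 1].max(), grid_resolution)
    xx, yy = np.meshgrid(gx, gy)
    proba = clf.predict_proba(np.column_stack([xx.ravel(), yy.ravel()]))
    if positive is None:
        col = len(clf.classes_) - 1
    else:
        col = int(np.flatnonzero(clf.classes_ == positive)[0])
    return xx, yy, proba[:, col].reshape(xx.shape)
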