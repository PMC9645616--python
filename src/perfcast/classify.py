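"""Cross-validated classification error of the four base classifiers (Step II).

The error of interest is the plain misclassification rate under stratified
10-fold cross-validation — an adequate performance measure here because the
simulated (and balanced real) datasets have equal class sizes. All four
classifiers are evaluated on the *same* fold assignment so their per-dataset
errors are directly comparable.

Base learners and their fixed hyperparameters:

* RF  — random forest, 500 trees, sqrt(d) candidate features per split
* SVM — radial-basis kernel, C = 1, kernel width 1 / (d * var(X))
* LDA — linear discriminant analysis; an automatic shrinkage estimator of the
  within-class covariance is used whenever the fold-train sample count does
  not exceed the feature count (the covariance would otherwise be singular)
* KNN — k = 5 nearest neighbors, Euclidean distance

Features are standardized by the training fold's mean and sd for the
distance/margin-based learners (SVM, KNN, LDA); trees are scale-invariant and
receive the raw values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .simdata import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSIFIER_NAMES",
    "ClassifierSpec",
    "ErrorProfile",
    "stratified_folds",
    "cv_error",
    "error_profile",
]

CLASSIFIER_NAMES = ("RF", "SVM", "LDA", "KNN")


@dataclass(frozen=True)
class ClassifierSpec:
    """A base classifier plus its fixed hyperparameters."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}")

    @property
    def standardize(self) -> bool:
        return self.name in ("SVM", "KNN", "LDA")

    def build(self, n_train: int, d: int, seed: int):
        h = self.hyperparameters
        if self.name == "RF":
            return RandomForestClassifier(
                n_estimators=h.get("n_trees", 500),
                max_features="sqrt",
                random_state=seed,
            )
        if self.name == "SVM":
            return SVC(kernel=h.get("kernel", "rbf"), C=h.get("C", 1.0), gamma="scale")
        if self.name == "KNN":
            return KNeighborsClassifier(n_neighbors=h.get("k", 5))
        # LDA: shrinkage fallback when the within-class covariance is singular
        if n_train <= d + 1:
            logger.debug("LDA: n_train=%d <= d=%d, using shrinkage", n_train, d)
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        return LinearDiscriminantAnalysis(solver="svd")


def default_specs(
    rf_trees: int = 500, knn_k: int = 5, svm_c: float = 1.0
) -> dict[str, ClassifierSpec]:
    return {
        "RF": ClassifierSpec("RF", {"n_trees": rf_trees}),
        "SVM": ClassifierSpec("SVM", {"kernel": "rbf", "C": svm_c}),
        "LDA": ClassifierSpec("LDA"),
        "KNN": ClassifierSpec("KNN", {"k": knn_k}),
    }


def stratified_folds(
    y: np.ndarray, n_folds: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """Stratified fold assignment: a list of test-index arrays.

    Folds are size-balanced and preserve class proportions; if the smaller
    class has fewer members than ``n_folds``, the fold count is reduced to
    that size (logged).
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    min_count = int(counts.min())
    if min_count < n_folds:
        logger.warning(
            "reducing folds from %d to %d (smallest class)", n_folds, min_count
        )
        n_folds = min_count
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros_like(y), y)]


def cv_error(
    ds: LabeledDataset,
    spec: ClassifierSpec,
    folds: list[np.ndarray],
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Mean misclassification rate over folds, plus the per-fold errors."""
    X, y = ds.X, ds.y
    n = len(y)
    all_idx = np.arange(n)
    fold_errors = np.empty(len(folds))
    for i, test in enumerate(folds):
        train = np.setdiff1d(all_idx, test, assume_unique=False)
        X_tr, X_te = X[train], X[test]
        if spec.standardize:
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0, ddof=0)
            sd = np.where(sd > 0, sd, 1.0)
            X_tr = (X_tr - mu) / sd
            X_te = (X_te - mu) / sd
        model = spec.build(n_train=len(train), d=X.shape[1], seed=seed)
        model.fit(X_tr, y[train])
        pred = model.predict(X_te)
        fold_errors[i] = float(np.mean(pred != y[test]))
    return float(fold_errors.mean()), fold_errors


@dataclass
class ErrorProfile:
    """Cross-validated misclassification rates of one dataset."""

    name: str
    errors: dict[str, float]
    fold_errors: dict[str, np.ndarray]

    @property
    def sd(self) -> dict[str, float]:
        return {k: float(np.std(v, ddof=1)) for k, v in self.fold_errors.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dataset": self.name,
                "classifier": list(self.errors),
                "mean_error": [self.errors[c] for c in self.errors],
                "sd_error": [self.sd[c] for c in self.errors],
            }
        )


def error_profile(
    ds: LabeledDataset,
    seed: int = 0,
    n_folds: int = 10,
    specs: dict[str, ClassifierSpec] | None = None,
) -> ErrorProfile:
    """Evaluate all four base classifiers on the same stratified folds."""
    if specs is None:
        specs = default_specs()
    folds = stratified_folds(ds.y, n_folds=n_folds, seed=seed)
    errors: dict[str, float] = {}
    fold_errors: dict[str, np.ndarray] = {}
    for name in CLASSIFIER_NAMES:
        mean_err, per_fold = cv_error(ds, specs[name], folds, seed=seed)
        errors[name] = mean_err
        fold_errors[name] = per_fold
    return ErrorProfile(name=ds.name, errors=errors, fold_errors=fold_errors)
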