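"""Meta-regression (Step III): predict classification error from meta-features.

The *meta-dataset* has one row per dataset: the meta-feature vector X and the
four observed cross-validated classification errors Y. Three regression
models predict each error column:

* linear — ordinary least squares (rank-aware, see below),
* rf — random forest with the number of candidate split variables (``mtry``)
  tuned over a 5-point grid between 2 and p by 10-fold cross-validation,
* bayes_glm — Bayesian linear regression with weakly-informative Gaussian
  priors estimated by evidence maximization.

R-squared is reported as the squared Pearson correlation between predictions
and observations (constant predictions score 0), matching the convention of
mainstream resampling frameworks; this keeps near-zero values non-negative
where the 1 - SSres/SStot definition would go negative. The latter is
available as a secondary diagnostic.

All three regressors are scikit-learn compatible estimators (``fit`` /
``predict`` / ``get_params``) so they compose with pipelines and model
selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import BayesianRidge
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .classify import CLASSIFIER_NAMES, ErrorProfile

logger = logging.getLogger(__name__)

__all__ = [
    "MetaDataset",
    "assemble_meta_dataset",
    "split_holdout",
    "r2_correlation",
    "coefficient_of_determination",
    "evaluate_r2",
    "mtry_grid",
    "LinearMetaRegressor",
    "RandomForestMetaRegressor",
    "BayesianGLMMetaRegressor",
    "MODEL_NAMES",
    "make_regressor",
]

MODEL_NAMES = ("linear", "rf", "bayes_glm")


@dataclass
class MetaDataset:
    """Rows = datasets; X = meta-features, Y = observed classifier errors."""

    X: pd.DataFrame
    Y: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.Y.index):
            raise ValueError("X and Y must be row-aligned")
        if self.X.isna().any().any() or self.Y.isna().any().any():
            raise ValueError("meta-dataset must be complete")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.X, self.Y], axis=1)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="dataset")

    @classmethod
    def from_tsv(cls, path) -> "MetaDataset":
        df = pd.read_csv(path, sep="\t", index_col="dataset").rename_axis(None)
        y_cols = [f"error_{c}" for c in CLASSIFIER_NAMES]
        return cls(X=df.drop(columns=y_cols), Y=df[y_cols])


def assemble_meta_dataset(
    vectors: pd.DataFrame, profiles: list[ErrorProfile]
) -> MetaDataset:
    """Join characteristic vectors with error profiles on the dataset id.

    Zero-variance meta-feature columns carry no information for regression
    and are dropped (logged).
    """
    err = pd.DataFrame(
        {f"error_{c}": {p.name: p.errors[c] for p in profiles} for c in CLASSIFIER_NAMES}
    )
    missing = set(vectors.index).symmetric_difference(err.index)
    if missing:
        raise ValueError(f"dataset ids do not match: {sorted(missing)[:5]}")
    err = err.loc[vectors.index]
    variances = vectors.var(axis=0, ddof=0)
    constant = variances[variances == 0].index.tolist()
    if constant:
        logger.info("dropping %d zero-variance meta-features: %s",
                    len(constant), constant[:8])
    X = vectors.drop(columns=constant)
    return MetaDataset(X=X, Y=err)


def split_holdout(
    meta: MetaDataset, fraction: float = 0.25, seed: int = 0
) -> tuple[MetaDataset, MetaDataset]:
    """Random disjoint train/test split with ceil(fraction * n) test rows."""
    if meta.n < 8:
        raise ValueError("need at least 8 datasets to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(meta.n)
    n_test = math.ceil(fraction * meta.n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    return (
        MetaDataset(meta.X.iloc[train_idx], meta.Y.iloc[train_idx]),
        MetaDataset(meta.X.iloc[test_idx], meta.Y.iloc[test_idx]),
    )


def r2_correlation(y_pred: np.ndarray, y_obs: np.ndarray) -> float:
    """Squared Pearson correlation; 0 for constant predictions."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_obs = np.asarray(y_obs, dtype=float)
    if np.allclose(y_pred, y_pred[0]) or np.allclose(y_obs, y_obs[0]):
        return 0.0
    r = np.corrcoef(y_pred, y_obs)[0, 1]
    return float(r * r) if np.isfinite(r) else 0.0


def coefficient_of_determination(y_pred: np.ndarray, y_obs: np.ndarray) -> float:
    """Secondary diagnostic: 1 - SSres/SStot (can be negative)."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = ((y_obs - y_obs.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    return float(1.0 - ((y_obs - y_pred) ** 2).sum() / ss_tot)


def evaluate_r2(model, X_test, y_test) -> float:
    """Hold-out R-squared (squared-correlation convention)."""
    return r2_correlation(model.predict(np.asarray(X_test, dtype=float)),
                          np.asarray(y_test, dtype=float))


def mtry_grid(p: int, n_points: int = 5) -> list[int]:
    """Evenly spaced candidate mtry values between 2 and p."""
    if p < 2:
        raise ValueError("need at least 2 predictors")
    grid = np.unique(np.floor(np.linspace(2, p, n_points)).astype(int))
    return [int(v) for v in grid]


class LinearMetaRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares with rank-aware coefficient handling.

    When p >= n (common for meta-datasets), the design is rank-deficient.
    The fit keeps the first ``min(rank, n - 2)`` columns of the pivoted QR
    decomposition — mirroring how pivoting-based least squares drops aliased
    columns — and treats the remaining coefficients as aliased (coefficient
    and t-statistic 0). Capping at n - 2 keeps at least one residual degree
    of freedom so coefficient standard errors stay finite.

    Fitted attributes: ``coef_``, ``intercept_``, ``t_values_`` (|t| is the
    linear model's variable-importance score), ``used_columns_``.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        self.n_features_in_ = p
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns)
        design = np.column_stack([np.ones(n), X])
        _, R, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        rank = int((diag > tol).sum())
        n_use = min(rank, n - 2)
        # always keep the intercept; fill remaining slots by pivot order
        keep = [0] + [c for c in piv[:n_use] if c != 0][: n_use - 1]
        D = design[:, keep]
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ beta
        df_resid = n - len(keep)
        sigma2 = float(resid @ resid) / df_resid if df_resid > 0 else np.nan
        xtx_inv = np.linalg.pinv(D.T @ D)
        se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))

        coef = np.zeros(p)
        tvals = np.zeros(p)
        for pos, col in enumerate(keep):
            if col == 0:
                self.intercept_ = float(beta[pos])
                continue
            coef[col - 1] = beta[pos]
            tvals[col - 1] = beta[pos] / se[pos] if se[pos] > 0 else 0.0
        self.coef_ = coef
        self.t_values_ = tvals
        self.used_columns_ = np.array([c - 1 for c in keep if c != 0])
        if len(keep) < rank + 0 or n_use < p:
            logger.debug("linear fit kept %d of %d predictors (n=%d)", len(keep) - 1, p, n)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


class BayesianGLMMetaRegressor(RegressorMixin, BaseEstimator):
    """Bayesian linear regression with Gaussian priors (evidence maximization).

    A thin wrapper over ridge-style Bayesian regression; predictors are
    standardized internally so the common prior scale is meaningful across
    heterogeneously-scaled meta-features.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.n_features_in_ = X.shape[1]
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        self.model_ = BayesianRidge()
        self.model_.fit((X - self._mu) / self._sd, y)
        self.coef_ = self.model_.coef_ / self._sd
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        return self.model_.predict((X - self._mu) / self._sd)


class RandomForestMetaRegressor(RegressorMixin, BaseEstimator):
    """Random-forest regression with cross-validated mtry tuning.

    ``fit`` evaluates each candidate mtry (5 values evenly spaced between 2
    and p) by ``cv``-fold cross-validation on the training data, recording
    per-fold RMSE and squared-correlation R-squared; the mtry with the best
    mean R-squared is refit on the full training data.

    Fitted attributes
    -----------------
    tuning_table_ : DataFrame with columns mtry, RMSE, R2, R2SD.
    best_mtry_ : selected number of candidate split variables.
    model_ : the refit ``RandomForestRegressor``.
    feature_importances_ : impurity-decrease importances of the refit forest.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        n_grid: int = 5,
        cv: int = 10,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.n_grid = n_grid
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        self.n_features_in_ = p
        grid = mtry_grid(p, self.n_grid)
        n_splits = min(self.cv, n)
        kf = KFold(n_splits=n_splits, shuffle=True, random_state=self.random_state)
        folds = list(kf.split(X))
        rows = []
        for mtry in grid:
            rmse_folds, r2_folds = [], []
            for train, test in folds:
                rf = RandomForestRegressor(
                    n_estimators=self.n_estimators,
                    max_features=mtry,
                    random_state=self.random_state,
                )
                rf.fit(X[train], y[train])
                pred = rf.predict(X[test])
                rmse_folds.append(float(np.sqrt(np.mean((pred - y[test]) ** 2))))
                r2_folds.append(r2_correlation(pred, y[test]))
            rows.append(
                {
                    "mtry": mtry,
                    "RMSE": float(np.mean(rmse_folds)),
                    "R2": float(np.mean(r2_folds)),
                    "R2SD": float(np.std(r2_folds, ddof=1)),
                }
            )
        self.tuning_table_ = pd.DataFrame(rows)
        best = self.tuning_table_["R2"].idxmax()
        self.best_mtry_ = int(self.tuning_table_.loc[best, "mtry"])
        self.best_cv_r2_ = float(self.tuning_table_.loc[best, "R2"])
        self.model_ = RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_features=self.best_mtry_,
            random_state=self.random_state,
        )
        self.model_.fit(X, y)
        self.feature_importances_ = self.model_.feature_importances_
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))


def make_regressor(model: str, seed: int = 0, rf_trees: int = 500, cv: int = 10):
    """Factory for the three meta-regression models."""
    if model == "linear":
        return LinearMetaRegressor()
    if model == "rf":
        return RandomForestMetaRegressor(
            n_estimators=rf_trees, cv=cv, random_state=seed
        )
    if model == "bayes_glm":
        return BayesianGLMMetaRegressor()
    raise ValueError(f"unknown regression model {model!r}")
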