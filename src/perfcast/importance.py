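"""Variable-importance rankings and their cross-simulation comparison.

The linear model's importance is the absolute t-statistic of each
coefficient; the random forest's is the accumulated impurity (SSE) decrease.
Both are min-max scaled to [0, 100] so rankings are comparable across models
and simulations. Rankings from different simulations are compared by
Spearman correlation of the full importance vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metaregress import LinearMetaRegressor, RandomForestMetaRegressor

__all__ = [
    "ImportanceRanking",
    "lm_importance",
    "rf_importance",
    "top_k",
    "ranking_correlation",
]


@dataclass
class ImportanceRanking:
    """Named importance scores scaled so the maximum is 100."""

    model: str
    target: str
    scores: pd.Series          # index = meta-feature names, values in [0, 100]

    def __post_init__(self) -> None:
        # normalize on construction so the invariant (max = 100 unless all
        # zero) holds for any raw score vector; idempotent
        self.scores = pd.Series(
            _scale(self.scores.to_numpy()), index=self.scores.index
        )

    def to_frame(self) -> pd.DataFrame:
        ordered = top_k(self, k=len(self.scores))
        return pd.DataFrame(
            {
                "name": [n for n, _ in ordered],
                "score": [s for _, s in ordered],
                "rank": np.arange(1, len(ordered) + 1),
            }
        )


def _scale(raw: np.ndarray) -> np.ndarray:
    raw = np.abs(np.asarray(raw, dtype=float))
    top = raw.max() if len(raw) else 0.0
    return (raw / top) * 100.0 if top > 0 else raw


def lm_importance(
    model: LinearMetaRegressor, feature_names, target: str = ""
) -> ImportanceRanking:
    """|t| of each coefficient, scaled to [0, 100]; aliased coefficients 0."""
    scores = pd.Series(_scale(model.t_values_), index=list(feature_names))
    return ImportanceRanking("linear", target, scores)


def rf_importance(
    model: RandomForestMetaRegressor, feature_names, target: str = ""
) -> ImportanceRanking:
    """Impurity-decrease importance of the tuned forest, scaled to [0, 100]."""
    scores = pd.Series(_scale(model.feature_importances_), index=list(feature_names))
    return ImportanceRanking("rf", target, scores)


def top_k(r: ImportanceRanking, k: int = 15) -> list[tuple[str, float]]:
    """Top-k features by descending score; ties broken by name."""
    if k > len(r.scores):
        raise ValueError("k exceeds the number of features")
    order = sorted(r.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(name, float(score)) for name, score in order[:k]]


def ranking_correlation(
    rankings: dict[str, ImportanceRanking | pd.Series]
) -> pd.DataFrame:
    """Pairwise Spearman correlation of full importance vectors.

    All rankings must cover the identical feature-name set; ties get average
    ranks (the scipy default).
    """
    series = {
        name: (r.scores if isinstance(r, ImportanceRanking) else r)
        for name, r in rankings.items()
    }
    names = list(series)
    ref = set(series[names[0]].index)
    for nm in names[1:]:
        if set(series[nm].index) != ref:
            raise ValueError(f"feature-name set of {nm!r} does not match")
    cols = sorted(ref)
    M = np.vstack([series[nm][cols].to_numpy() for nm in names])
    out = np.eye(len(names))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rho = stats.spearmanr(M[i], M[j]).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=names, columns=names)
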