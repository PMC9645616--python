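"""Dataset characterization (Step I): the meta-feature vector.

A labeled expression dataset is summarized by a fixed-length named vector of
*meta-features* covering three aspects:

1. univariate discriminatory ability — distributional summaries of three
   filter scores (two-sample t statistic, information gain, ReliefF) plus
   counts of features below raw/adjusted p-value thresholds,
2. correlation structure — global descriptors of the thresholded
   feature-correlation network (density, transitivity, diameter, ...),
3. sub-cluster structure — internal cluster validity indices of k-means
   partitions of the samples for several k.

These vectors are the predictors from which classifier performance is later
regressed; every entry is finite by construction (degenerate cases follow the
documented conventions) so downstream regression needs no imputation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)
from statsmodels.stats.multitest import multipletests

from .simdata import LabeledDataset, _two_sample_t

logger = logging.getLogger(__name__)

__all__ = [
    "FilterScoreSet",
    "t_scores",
    "info_gain",
    "relieff",
    "summarize_scores",
    "bh_adjust",
    "pvalue_threshold_counts",
    "correlation_graph",
    "graph_descriptors",
    "cluster_indices",
    "characterize",
    "DatasetCharacterizer",
]

PERCENTILES = (2, 5, 10, 25, 50, 75, 90, 92, 95, 98)
P_THRESHOLDS = (0.001, 0.01, 0.05, 0.1)


@dataclass
class FilterScoreSet:
    """Per-feature relevance scores from one filter method."""

    method: str                      # "tt", "ig" or "rf"
    scores: np.ndarray
    pvalues: np.ndarray | None = None


def t_scores(X: np.ndarray, y: np.ndarray) -> FilterScoreSet:
    """Pooled-variance two-sample Student t per feature (group1 - group2).

    Two-sided p-values with n - 2 degrees of freedom. A feature with zero
    variance in both groups gets t = 0, p = 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n1, n2 = int((y == 1).sum()), int((y == 0).sum())
    if min(n1, n2) < 2:
        raise ValueError("each class needs at least 2 samples")
    t = _two_sample_t(X, y)
    df = n1 + n2 - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(t == 0.0, np.where(_pooled_sd_zero(X, y), 1.0, p), p)
    return FilterScoreSet("tt", t, p)


def _pooled_sd_zero(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    g1, g2 = X[y == 1], X[y == 0]
    return (g1.var(axis=0, ddof=1) + g2.var(axis=0, ddof=1)) == 0.0


def info_gain(X: np.ndarray, y: np.ndarray, n_bins: int | None = None) -> FilterScoreSet:
    """Information gain of the class given each feature, in bits.

    Continuous features are discretized by equal-frequency binning into
    ``min(10, ceil(sqrt(n)))`` bins; constant features score 0. Bounded by the
    class entropy H(y).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("labels are degenerate")
    if n_bins is None:
        n_bins = min(10, math.ceil(math.sqrt(n)))
    h_y = _entropy_bits(np.bincount(y.astype(int)))
    scores = np.empty(d)
    for j in range(d):
        x = X[:, j]
        edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
        bins = np.digitize(x, edges)
        h_cond = 0.0
        for b in np.unique(bins):
            mask = bins == b
            h_cond += mask.mean() * _entropy_bits(np.bincount(y[mask].astype(int)))
        scores[j] = max(0.0, h_y - h_cond)
    return FilterScoreSet("ig", scores)


def _entropy_bits(counts: np.ndarray) -> float:
    counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def relieff(X: np.ndarray, y: np.ndarray, k: int = 10) -> FilterScoreSet:
    """ReliefF feature weights with every instance as an anchor (m = n).

    For each anchor, the k nearest same-class *hits* decrease a feature's
    weight by its normalized value difference and the k nearest *misses* of
    each other class increase it, weighted by that class's prior. Per-feature
    differences are range-normalized, so weights lie in [-1, 1]. If a class
    has too few members, k is reduced for it (with a logged warning).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    denom = np.where(span > 0, span, 1.0)
    Z = (X - X.min(axis=0)) / denom
    Z[:, span == 0] = 0.0

    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    count_of = dict(zip(classes, counts))
    if any(c <= k for c in counts):
        logger.warning(
            "relieff: a class has <= k=%d samples; reducing neighbor count", k
        )

    D = cdist(Z, Z, metric="cityblock")
    np.fill_diagonal(D, np.inf)
    W = np.zeros(d)
    for i in range(n):
        ci = y[i]
        for c in classes:
            members = np.flatnonzero(y == c)
            if c == ci:
                members = members[members != i]
            k_eff = min(k, len(members))
            if k_eff == 0:
                continue
            nearest = members[np.argsort(D[i, members], kind="stable")[:k_eff]]
            contrib = np.abs(Z[i] - Z[nearest]).sum(axis=0) / (n * k_eff)
            if c == ci:
                W -= contrib
            else:
                W += priors[c] / (1.0 - priors[ci]) * contrib
    return FilterScoreSet("rf", W)


def summarize_scores(s: FilterScoreSet | np.ndarray, prefix: str | None = None) -> dict[str, float]:
    """Distributional summary of one filter-score vector.

    Emits, prefixed by the filter tag: count of valid cases, mean, 10%-trimmed
    mean, median, sd, scaled MAD, min, max, range, skew, excess kurtosis,
    standard error and the percentile grid (suffix ``pc``). Constant scores
    get skew = kurtosis = 0.
    """
    if isinstance(s, FilterScoreSet):
        prefix = prefix or s.method
        x = np.asarray(s.scores, dtype=float)
    else:
        x = np.asarray(s, dtype=float)
        if prefix is None:
            raise ValueError("prefix required for a bare array")
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("need at least 2 finite scores")
    sd = float(np.std(x, ddof=1))
    out = {
        f"{prefix}_n": float(len(x)),
        f"{prefix}_mean": float(np.mean(x)),
        f"{prefix}_trimmed": float(stats.trim_mean(x, 0.1)),
        f"{prefix}_median": float(np.median(x)),
        f"{prefix}_sd": sd,
        f"{prefix}_mad": float(stats.median_abs_deviation(x, scale="normal")),
        f"{prefix}_min": float(np.min(x)),
        f"{prefix}_max": float(np.max(x)),
        f"{prefix}_range": float(np.ptp(x)),
        f"{prefix}_skew": float(stats.skew(x)) if sd > 0 else 0.0,
        f"{prefix}_kurtosis": float(stats.kurtosis(x)) if sd > 0 else 0.0,
        f"{prefix}_se": sd / math.sqrt(len(x)),
    }
    for q in PERCENTILES:
        out[f"{prefix}_{q:02d}pc"] = float(np.percentile(x, q))
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0 or np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pvalue_threshold_counts(p: np.ndarray, p_adj: np.ndarray) -> dict[str, float]:
    """Counts of features below each p-value threshold (strict <).

    ``npthTotal`` sums the raw-p counts; ``npthTotalSum`` sums raw plus
    adjusted counts.
    """
    p = np.asarray(p, dtype=float)
    p_adj = np.asarray(p_adj, dtype=float)
    if p.shape != p_adj.shape:
        raise ValueError("p and p_adj must have equal length")
    out: dict[str, float] = {}
    for thr in P_THRESHOLDS:
        out[f"pthr{thr}"] = float((p < thr).sum())
    for thr in P_THRESHOLDS:
        out[f"pthrAdj{thr}"] = float((p_adj < thr).sum())
    raw_total = sum(out[f"pthr{thr}"] for thr in P_THRESHOLDS)
    adj_total = sum(out[f"pthrAdj{thr}"] for thr in P_THRESHOLDS)
    out["npthTotal"] = raw_total
    out["npthTotalSum"] = raw_total + adj_total
    return out


def correlation_graph(X: np.ndarray, tau: float = 0.7) -> nx.Graph:
    """Undirected feature graph with edges where |Pearson r| >= tau.

    Constant features have no well-defined correlation and get no edges.
    """
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    if d < 2:
        raise ValueError("need at least 2 features")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    G = nx.Graph()
    G.add_nodes_from(range(d))
    iu, ju = np.triu_indices(d, k=1)
    mask = np.abs(r[iu, ju]) >= tau
    G.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
    return G


def graph_descriptors(G: nx.Graph) -> dict[str, float]:
    """Global topological descriptors of the correlation network.

    Density, reciprocity (1 by convention for undirected graphs), global
    transitivity, and diameter / mean shortest-path length over reachable
    pairs only (0 for an edgeless graph).
    """
    d = G.number_of_nodes()
    if d < 2:
        raise ValueError("graph must have at least 2 vertices")
    density = 2.0 * G.number_of_edges() / (d * (d - 1))
    transitivity = nx.transitivity(G)
    diameter = 0.0
    dist_sum = 0.0
    n_pairs = 0
    for comp in nx.connected_components(G):
        if len(comp) < 2:
            continue
        sub = G.subgraph(comp)
        for src, lengths in nx.all_pairs_shortest_path_length(sub):
            for dst, length in lengths.items():
                if dst != src:
                    dist_sum += length
                    n_pairs += 1
                    diameter = max(diameter, float(length))
    mean_distance = dist_sum / n_pairs if n_pairs else 0.0
    return {
        "graph_density": density,
        "graph_reciprocity": 1.0,
        "graph_transitivity": float(transitivity),
        "graph_diameter": diameter,
        "graph_mean_distance": mean_distance,
    }


# ---------------------------------------------------------------------------
# internal cluster validity indices (clusterCrit-style definitions)

CLUSTER_INDEX_NAMES = (
    "ball_hall",
    "c_index",
    "calinski_harabasz",
    "davies_bouldin",
    "dunn",
    "gdi31",
    "silhouette",
    "xie_beni",
)


def _cluster_index_values(X: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    n = len(X)
    ks = np.unique(labels)
    centroids = np.vstack([X[labels == c].mean(axis=0) for c in ks])
    D = squareform(pdist(X))

    # within-cluster dispersion
    wgss_per = []
    for idx, c in enumerate(ks):
        pts = X[labels == c]
        wgss_per.append(((pts - centroids[idx]) ** 2).sum(axis=1).mean() if len(pts) else 0.0)
    ball_hall = float(np.mean(wgss_per))

    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    within_mask = same[iu]
    all_d = D[iu]
    nw = int(within_mask.sum())
    if nw and nw < len(all_d):
        s_w = float(all_d[within_mask].sum())
        d_sorted = np.sort(all_d)
        s_min = float(d_sorted[:nw].sum())
        s_max = float(d_sorted[-nw:].sum())
        c_index = (s_w - s_min) / (s_max - s_min) if s_max > s_min else 0.0
    else:
        c_index = 0.0

    between = all_d[~within_mask]
    within = all_d[within_mask]
    max_diam = float(within.max()) if len(within) else 0.0
    dunn = float(between.min()) / max_diam if len(between) and max_diam > 0 else 0.0

    # generalized Dunn index, between-measure 3 (mean pairwise between-cluster
    # distance), within-measure 1 (cluster diameter)
    min_between3 = np.inf
    for a in range(len(ks)):
        for b in range(a + 1, len(ks)):
            da = D[np.ix_(labels == ks[a], labels == ks[b])]
            if da.size:
                min_between3 = min(min_between3, float(da.mean()))
    gdi31 = float(min_between3) / max_diam if np.isfinite(min_between3) and max_diam > 0 else 0.0

    sq_dist_to_centroid = sum(
        ((X[labels == c] - centroids[i]) ** 2).sum() for i, c in enumerate(ks)
    )
    cd = pdist(centroids) ** 2
    xie_beni = float(sq_dist_to_centroid / (n * cd.min())) if len(cd) and cd.min() > 0 else 0.0

    return {
        "ball_hall": ball_hall,
        "c_index": float(c_index),
        "calinski_harabasz": float(calinski_harabasz_score(X, labels)),
        "davies_bouldin": float(davies_bouldin_score(X, labels)),
        "dunn": dunn,
        "gdi31": gdi31,
        "silhouette": float(silhouette_score(X, labels)),
        "xie_beni": xie_beni,
    }


def cluster_indices(
    X: np.ndarray,
    k_set: tuple[int, ...] = (2, 3, 4),
    seed: int = 0,
) -> dict[str, float]:
    """k-means partitions of the samples and their validity indices.

    For each k, runs k-means (k-means++ init, 10 restarts, fixed seed) and
    emits eight indices named ``k{k}_{index}``.
    """
    X = np.asarray(X, dtype=float)
    if len(X) <= max(k_set):
        raise ValueError("need more samples than the largest k")
    out: dict[str, float] = {}
    for k in k_set:
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < k:
            km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed + 1)
            labels = km.fit_predict(X)
            if len(np.unique(labels)) < k:
                raise RuntimeError(f"k-means produced an empty cluster for k={k}")
        for name, value in _cluster_index_values(X, labels).items():
            out[f"k{k}_{name}"] = value
    return out


def characterize(
    ds: LabeledDataset,
    tau: float = 0.7,
    k_set: tuple[int, ...] = (2, 3, 4),
    relieff_k: int = 10,
    cluster_seed: int = 0,
) -> pd.Series:
    """Compute the full meta-feature vector of one dataset.

    Concatenates the three filter-score summaries, the p-value threshold
    counts, the correlation-network descriptors and the cluster indices, in a
    fixed name order. Deterministic given the dataset and ``cluster_seed``.
    """
    X, y = ds.X, ds.y
    tt = t_scores(X, y)
    ig = info_gain(X, y)
    rf = relieff(X, y, k=relieff_k)
    out: dict[str, float] = {}
    out.update(summarize_scores(tt))
    out.update(summarize_scores(ig))
    out.update(summarize_scores(rf))
    out.update(pvalue_threshold_counts(tt.pvalues, bh_adjust(tt.pvalues)))
    out.update(graph_descriptors(correlation_graph(X, tau=tau)))
    out.update(cluster_indices(X, k_set=k_set, seed=cluster_seed))
    return pd.Series(out, name=ds.name)


class DatasetCharacterizer(TransformerMixin, BaseEstimator):
    """Transformer mapping labeled datasets to their meta-feature vectors.

    Stateless (fit is a no-op, kept for pipeline compatibility); `transform`
    accepts a single :class:`LabeledDataset` or an iterable of them and
    returns a one-row-per-dataset DataFrame with a stable column order.

    Parameters
    ----------
    tau : absolute Pearson correlation threshold for the feature network.
    k_set : cluster counts for the k-means validity indices.
    relieff_k : neighbor count for ReliefF.
    cluster_seed : seed of the k-means restarts (keeps vectors deterministic).
    """

    def __init__(
        self,
        tau: float = 0.7,
        k_set: tuple[int, ...] = (2, 3, 4),
        relieff_k: int = 10,
        cluster_seed: int = 0,
    ):
        self.tau = tau
        self.k_set = k_set
        self.relieff_k = relieff_k
        self.cluster_seed = cluster_seed

    def fit(self, X=None, y=None) -> "DatasetCharacterizer":
        return self

    def transform(self, X) -> pd.DataFrame:
        datasets = [X] if isinstance(X, LabeledDataset) else list(X)
        rows = [
            characterize(
                ds,
                tau=self.tau,
                k_set=tuple(self.k_set),
                relieff_k=self.relieff_k,
                cluster_seed=self.cluster_seed,
            )
            for ds in datasets
        ]
        return pd.DataFrame(rows)
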