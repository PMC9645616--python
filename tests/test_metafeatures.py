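"""Meta-feature oracles: textbook t statistics, hand-computed BH and counts,
enumerated graph descriptors, brute-force ReliefF, and vector stability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfcast.metafeatures import (
    DatasetCharacterizer,
    bh_adjust,
    characterize,
    cluster_indices,
    correlation_graph,
    graph_descriptors,
    info_gain,
    pvalue_threshold_counts,
    relieff,
    summarize_scores,
    t_scores,
)
from perfcast.simdata import LabeledDataset

import networkx as nx


class TestTScores:
    def test_identical_groups(self):
        X = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        y = np.array([1, 1, 1, 0, 0, 0])
        s = t_scores(X, y)
        assert s.scores[0] == 0.0
        assert s.pvalues[0] == 1.0

    def test_textbook_pooled_t(self):
        # pooled t for (5,6,7) vs (1,2,3): t = 4 / sqrt(2/3)
        X = np.array([[5.0], [6.0], [7.0], [1.0], [2.0], [3.0]])
        y = np.array([1, 1, 1, 0, 0, 0])
        s = t_scores(X, y)
        assert s.scores[0] == pytest.approx(4.898979, abs=1e-5)
        assert s.pvalues[0] == pytest.approx(0.00804, abs=1e-4)

    def test_label_swap_flips_sign(self, rng):
        X = rng.normal(size=(20, 5))
        y = np.repeat([1, 0], 10)
        np.testing.assert_allclose(
            t_scores(X, y).scores, -t_scores(X, 1 - y).scores
        )

    def test_zero_variance_feature(self):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        y = np.repeat([1, 0], 4)
        s = t_scores(X, y)
        assert s.scores[0] == 0.0 and s.pvalues[0] == 1.0


class TestInfoGain:
    def test_feature_identical_to_class(self):
        y = np.repeat([0, 1], 20)
        X = y.astype(float)[:, None]
        assert info_gain(X, y).scores[0] == pytest.approx(1.0, abs=1e-9)

    def test_independent_feature_vanishes(self, rng):
        y = np.repeat([0, 1], 500)
        X = rng.normal(size=(1000, 3))
        assert np.all(info_gain(X, y).scores < 0.05)

    def test_bounded_by_class_entropy(self, rng):
        y = np.repeat([0, 1], 15)
        X = rng.normal(size=(30, 10))
        X[:, 0] = y  # perfectly informative
        scores = info_gain(X, y).scores
        assert np.all(scores <= 1.0 + 1e-12)
        assert np.all(scores >= 0.0)

    def test_constant_feature_scores_zero(self):
        X = np.ones((20, 1))
        y = np.repeat([0, 1], 10)
        assert info_gain(X, y).scores[0] == 0.0


def _brute_force_relief_binary(X, y, k):
    """Independent reference: textbook ReliefF for binary classes."""
    n, d = X.shape
    span = X.max(0) - X.min(0)
    span = np.where(span > 0, span, 1.0)
    Z = (X - X.min(0)) / span
    W = np.zeros(d)
    priors = {c: np.mean(y == c) for c in np.unique(y)}
    for i in range(n):
        dists = np.abs(Z - Z[i]).sum(axis=1)
        for c in np.unique(y):
            members = [j for j in range(n) if y[j] == c and j != i]
            members.sort(key=lambda j: dists[j])
            near = members[: min(k, len(members))]
            for j in near:
                contrib = np.abs(Z[i] - Z[j]) / (n * len(near))
                if c == y[i]:
                    W -= contrib
                else:
                    W += priors[c] / (1 - priors[y[i]]) * contrib
    return W


class TestReliefF:
    def test_matches_brute_force(self, rng):
        X = rng.normal(size=(10, 4))
        y = np.repeat([0, 1], 5)
        np.testing.assert_allclose(
            relieff(X, y, k=3).scores, _brute_force_relief_binary(X, y, 3)
        )

    def test_separating_feature_wins(self, rng):
        X = rng.normal(size=(10, 5))
        y = np.repeat([0, 1], 5)
        X[:, 0] = np.where(y == 0, rng.uniform(0, 1, 10), rng.uniform(5, 6, 10))
        scores = relieff(X, y, k=3).scores
        assert scores[0] == scores.max()

    def test_duplicate_features_equal_weight(self, rng):
        X = rng.normal(size=(12, 3))
        X[:, 2] = X[:, 0]
        y = np.repeat([0, 1], 6)
        scores = relieff(X, y, k=3).scores
        assert scores[0] == pytest.approx(scores[2])

    def test_constant_features_zero(self):
        X = np.ones((10, 3))
        y = np.repeat([0, 1], 5)
        np.testing.assert_allclose(relieff(X, y).scores, 0.0)

    def test_weights_bounded(self, rng):
        X = rng.normal(size=(30, 8))
        y = np.repeat([0, 1], 15)
        scores = relieff(X, y).scores
        assert np.all((scores >= -1) & (scores <= 1))


class TestSummarize:
    def test_hand_computed_summary(self):
        out = summarize_scores(np.array([1.0, 2, 3, 4, 5]), prefix="tt")
        assert out["tt_mean"] == 3.0
        assert out["tt_median"] == 3.0
        assert out["tt_sd"] == pytest.approx(1.5811, abs=1e-4)
        assert out["tt_range"] == 4.0
        assert out["tt_n"] == 5.0
        assert out["tt_se"] == pytest.approx(1.5811 / np.sqrt(5), abs=1e-4)

    def test_constant_scores_conventions(self):
        out = summarize_scores(np.full(10, 2.5), prefix="ig")
        assert out["ig_sd"] == 0.0
        assert out["ig_skew"] == 0.0
        assert out["ig_kurtosis"] == 0.0

    def test_median_percentile_agree(self, rng):
        x = rng.normal(size=101)
        out = summarize_scores(x, prefix="rf")
        assert out["rf_50pc"] == pytest.approx(out["rf_median"])

    def test_too_few_scores(self):
        with pytest.raises(ValueError):
            summarize_scores(np.array([1.0]), prefix="tt")


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_singleton_identity(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_never_decreases_and_order_preserving(self, p):
        adj = bh_adjust(np.array(p))
        assert np.all(adj >= np.array(p) - 1e-12)
        assert np.all((adj >= 0) & (adj <= 1))
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestThresholdCounts:
    def test_hand_counted_example(self):
        out = pvalue_threshold_counts(
            [0.0005, 0.02, 0.2], [0.0015, 0.06, 0.2]
        )
        assert out["pthr0.001"] == 1
        assert out["pthr0.01"] == 1
        assert out["pthr0.05"] == 2
        assert out["pthr0.1"] == 2
        assert out["pthrAdj0.001"] == 0
        assert out["pthrAdj0.01"] == 1
        assert out["pthrAdj0.05"] == 1
        assert out["pthrAdj0.1"] == 2
        assert out["npthTotal"] == 6
        assert out["npthTotalSum"] == 10

    def test_all_ones_gives_zeros(self):
        out = pvalue_threshold_counts(np.ones(5), np.ones(5))
        assert all(v == 0 for v in out.values())

    def test_counts_monotone_in_threshold(self, rng):
        p = rng.uniform(size=200)
        out = pvalue_threshold_counts(p, bh_adjust(p))
        raw = [out[f"pthr{t}"] for t in (0.001, 0.01, 0.05, 0.1)]
        adj = [out[f"pthrAdj{t}"] for t in (0.001, 0.01, 0.05, 0.1)]
        assert raw == sorted(raw) and adj == sorted(adj)
        # BH adjustment can only reduce counts
        assert all(a <= r for a, r in zip(adj, raw))


class TestCorrelationGraph:
    def test_duplicated_features_form_triangle(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([x, x, x])
        G = correlation_graph(X, tau=0.7)
        assert G.number_of_edges() == 3

    def test_independent_features_edgeless(self, rng):
        X = rng.normal(size=(1000, 10))
        assert correlation_graph(X, tau=0.7).number_of_edges() == 0

    def test_tau_zero_complete_graph(self, rng):
        X = rng.normal(size=(30, 4))
        assert correlation_graph(X, tau=0.0).number_of_edges() == 6

    def test_constant_feature_isolated(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        G = correlation_graph(X, tau=0.5)
        assert G.degree[0] == 0


class TestGraphDescriptors:
    def test_triangle(self):
        out = graph_descriptors(nx.complete_graph(3))
        assert out["graph_density"] == 1.0
        assert out["graph_transitivity"] == 1.0
        assert out["graph_diameter"] == 1.0
        assert out["graph_mean_distance"] == 1.0

    def test_path_graph_enumeration(self):
        out = graph_descriptors(nx.path_graph(3))
        assert out["graph_density"] == pytest.approx(2 / 3)
        assert out["graph_transitivity"] == 0.0
        assert out["graph_diameter"] == 2.0
        assert out["graph_mean_distance"] == pytest.approx(4 / 3)

    def test_edgeless_conventions(self):
        G = nx.empty_graph(5)
        out = graph_descriptors(G)
        assert out["graph_density"] == 0.0
        assert out["graph_transitivity"] == 0.0
        assert out["graph_diameter"] == 0.0
        assert out["graph_mean_distance"] == 0.0
        assert out["graph_reciprocity"] == 1.0

    def test_bounds(self, rng):
        X = rng.normal(size=(40, 12))
        out = graph_descriptors(correlation_graph(X, tau=0.3))
        assert 0.0 <= out["graph_density"] <= 1.0
        assert 0.0 <= out["graph_transitivity"] <= 1.0


class TestClusterIndices:
    def test_separated_blobs_high_silhouette(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (25, 4)), rng.normal(5, 0.3, (25, 4))])
        out = cluster_indices(X, k_set=(2,), seed=0)
        assert out["k2_silhouette"] > 0.7

    def test_c_index_in_unit_interval(self, rng):
        X = rng.normal(size=(40, 6))
        out = cluster_indices(X, k_set=(2, 3), seed=0)
        for k in (2, 3):
            assert 0.0 <= out[f"k{k}_c_index"] <= 1.0

    def test_all_indices_emitted(self, rng):
        X = rng.normal(size=(30, 5))
        out = cluster_indices(X, k_set=(2, 3, 4), seed=0)
        assert len(out) == 24
        assert all(np.isfinite(v) for v in out.values())


class TestCharacterize:
    def test_identical_datasets_identical_vectors(self, blob_dataset):
        a = characterize(blob_dataset)
        b = characterize(blob_dataset)
        pd.testing.assert_series_equal(a, b)

    def test_sample_permutation_stability(self, rng, noise_dataset):
        perm = rng.permutation(noise_dataset.n_samples)
        permuted = LabeledDataset(
            X=noise_dataset.X[perm],
            y=noise_dataset.y[perm],
            feature_names=noise_dataset.feature_names,
            name=noise_dataset.name,
        )
        a = characterize(noise_dataset)
        b = characterize(permuted)
        non_cluster = [n for n in a.index if not n.startswith("k")]
        np.testing.assert_allclose(a[non_cluster], b[non_cluster], atol=1e-10)

    def test_cluster_indices_stable_for_structured_data(self, rng, blob_dataset):
        # with unambiguous cluster structure the k=2 partition, and hence its
        # indices, do not depend on the sample order
        perm = rng.permutation(blob_dataset.n_samples)
        permuted = LabeledDataset(
            X=blob_dataset.X[perm],
            y=blob_dataset.y[perm],
            feature_names=blob_dataset.feature_names,
            name=blob_dataset.name,
        )
        a = cluster_indices(blob_dataset.X, k_set=(2,), seed=0)
        b = cluster_indices(permuted.X, k_set=(2,), seed=0)
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-6)

    def test_transformer_table(self, blob_dataset, noise_dataset):
        table = DatasetCharacterizer().transform([blob_dataset, noise_dataset])
        assert list(table.index) == ["blobs", "noise"]
        assert table.notna().all().all()
        assert not table.columns.duplicated().any()

    def test_discriminability_features_stochastically_larger(self):
        # across replicate simulations, datasets with differential expression
        # score higher on mean |t| and npthTotal than pure-noise datasets
        from scipy.stats import mannwhitneyu

        from perfcast.simdata import PartConfig, simulate_part

        y = np.repeat([1, 0], 15)
        rich_part = PartConfig(num_datasets=1, n_train=30, n_group1=15,
                               n_features=10, sd_tech=1, sd_biol=1,
                               diff_expr=True, fold_min=2.5)
        null_part = PartConfig(num_datasets=1, n_train=30, n_group1=15,
                               n_features=10, sd_tech=1, sd_biol=1,
                               diff_expr=False)
        stats_rich, stats_null = [], []
        for i in range(50):
            for part, sink in ((rich_part, stats_rich), (null_part, stats_null)):
                rng = np.random.default_rng([17, i, part.diff_expr])
                X, _, _ = simulate_part(part, y, rng)
                tt = t_scores(X, y)
                counts = pvalue_threshold_counts(tt.pvalues, bh_adjust(tt.pvalues))
                sink.append((np.abs(tt.scores).mean(), counts["npthTotal"]))
        for col in (0, 1):
            a = [s[col] for s in stats_rich]
            b = [s[col] for s in stats_null]
            assert mannwhitneyu(a, b, alternative="greater").pvalue < 0.01

    def test_discriminative_exceeds_noise(self, blob_dataset, noise_dataset):
        a = characterize(blob_dataset)
        b = characterize(noise_dataset)
        assert a["npthTotal"] > b["npthTotal"]
        assert abs(a["tt_mean"]) + a["tt_sd"] > abs(b["tt_mean"]) + b["tt_sd"]
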