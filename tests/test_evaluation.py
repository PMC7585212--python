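"""Cross-validated marker-set evaluation: folds, NCC, metrics, AoM ranks."""

import numpy as np
import pandas as pd
import pytest

from rankcorr import (
    CountMatrix,
    aom_rank,
    classification_metrics,
    clustering_metrics,
    cross_validated_evaluation,
    louvain_grid_cluster,
    log_normalize,
    make_folds,
    predict_ncc,
    train_ncc,
)


def separable_counts(n_per_class=10, seed=0):
    """Two classes, each with its own exclusively-expressed marker gene."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.repeat([0, 1], n_per_class)
    V = rng.integers(0, 3, size=(n, 6))
    V[:, 0] = np.where(y == 0, 60 + rng.integers(0, 5, n), 0)
    V[:, 1] = np.where(y == 1, 60 + rng.integers(0, 5, n), 0)
    return CountMatrix(V, gene_ids=[f"g{j}" for j in range(6)]), y


class TestMakeFolds:
    def test_even_split(self):
        f = make_folds(10, K=5, seed=0)
        sizes = np.bincount(f.fold_of_cell)[1:]
        np.testing.assert_array_equal(sizes, [2, 2, 2, 2, 2])

    def test_uneven_split_differs_by_at_most_one(self):
        f = make_folds(11, K=5, seed=3)
        sizes = sorted(np.bincount(f.fold_of_cell)[1:])
        assert sizes == [2, 2, 2, 2, 3]

    def test_deterministic_under_seed(self):
        a = make_folds(37, K=5, seed=11)
        b = make_folds(37, K=5, seed=11)
        np.testing.assert_array_equal(a.fold_of_cell, b.fold_of_cell)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            make_folds(4, K=5)


class TestNearestCentroids:
    def test_single_cell_classes_reproduce_their_rows(self):
        X, y = separable_counts(n_per_class=1)
        model = train_ncc(X, y, markers=list(X.gene_ids))
        L = log_normalize(X)
        np.testing.assert_allclose(model.centroids, L)

    def test_duplicated_training_set_leaves_centroids_unchanged(self):
        X, y = separable_counts(5)
        X2 = CountMatrix(
            np.vstack([X.dense(), X.dense()]), gene_ids=X.gene_ids
        )
        a = train_ncc(X, y, list(X.gene_ids))
        b = train_ncc(X2, np.concatenate([y, y]), list(X.gene_ids))
        np.testing.assert_allclose(a.centroids, b.centroids)

    def test_separated_classes_reclassified_perfectly(self):
        X, y = separable_counts(8)
        model = train_ncc(X, y, markers=["g0", "g1"])
        np.testing.assert_array_equal(predict_ncc(model, X), y)

    def test_cell_equal_to_a_centroid_gets_that_class(self):
        X, y = separable_counts(1)
        model = train_ncc(X, y, markers=list(X.gene_ids))
        pred = predict_ncc(model, X)
        np.testing.assert_array_equal(pred, y)

    def test_equidistant_tie_goes_to_lower_class_id(self):
        V = np.array([[4, 0], [0, 4], [2, 2]])
        X = CountMatrix(V, gene_ids=["a", "b"])
        model = train_ncc(X.subset_cells([0, 1]), np.array([0, 1]), ["a", "b"])
        pred = predict_ncc(model, X.subset_cells([2, 2]))
        assert pred[0] == 0

    def test_unknown_marker_rejected(self):
        X, y = separable_counts(3)
        with pytest.raises(KeyError):
            train_ncc(X, y, markers=["nope"])


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        m = classification_metrics([1, 2, 3], [1, 2, 3])
        assert (m["error"], m["weighted_precision"], m["mcc"]) == (0.0, 1.0, 1.0)

    def test_hand_confusion_matrix(self):
        m = classification_metrics([1, 1, 2, 2], [1, 2, 1, 2])
        assert m["error"] == pytest.approx(0.5)
        assert m["weighted_precision"] == pytest.approx(0.5)
        assert m["mcc"] == pytest.approx(0.0)

    def test_constant_prediction_is_no_information(self):
        m = classification_metrics([1, 1, 2, 2], [1, 1, 1, 1])
        assert m["mcc"] == pytest.approx(0.0)
        # the never-predicted class contributes precision 0
        assert m["weighted_precision"] == pytest.approx(0.25)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([], [])

    def test_ranges(self, rng):
        y = rng.integers(0, 4, 100)
        yhat = rng.integers(0, 4, 100)
        m = classification_metrics(y, yhat)
        assert 0 <= m["error"] <= 1 and 0 <= m["weighted_precision"] <= 1
        assert -1 <= m["mcc"] <= 1


class TestClusteringMetrics:
    def test_identical_partitions_score_one(self):
        m = clustering_metrics([0, 0, 1, 1, 2], [0, 0, 1, 1, 2])
        assert (m["ari"], m["ami"], m["fms"]) == (1.0, 1.0, 1.0)

    def test_relabeling_invariance(self):
        a = [0, 0, 1, 1, 2, 2]
        b = [7, 7, 3, 3, 9, 9]
        m = clustering_metrics(a, b)
        assert m["ari"] == pytest.approx(1.0) and m["fms"] == pytest.approx(1.0)
        assert m["ami"] == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a = rng.integers(0, 3, 60)
        b = rng.integers(0, 5, 60)
        m1, m2 = clustering_metrics(a, b), clustering_metrics(b, a)
        for key in ("ari", "ami", "fms"):
            assert m1[key] == pytest.approx(m2[key], abs=1e-12)

    def test_random_partitions_near_zero(self, rng):
        aris, amis = [], []
        for _ in range(25):
            a = rng.integers(0, 4, 200)
            b = rng.integers(0, 4, 200)
            m = clustering_metrics(a, b)
            aris.append(m["ari"])
            amis.append(m["ami"])
        assert abs(np.mean(aris)) < 0.05 and abs(np.mean(amis)) < 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            clustering_metrics([], [])


class TestLouvainGrid:
    def test_ground_truth_callable_scores_one_everywhere(self):
        X, y = separable_counts(10)
        calls = []

        def fake_cluster(adj, r):
            calls.append(r)
            return np.asarray(y)

        best = louvain_grid_cluster(
            X, list(X.gene_ids), k_neighbors=3, ground_truth=y, cluster_fn=fake_cluster
        )
        assert best == {"ari": 1.0, "ami": 1.0, "fms": 1.0}
        assert len(calls) == 30  # r = 0.1 .. 3.0 step 0.1

    def test_per_metric_maxima_are_independent(self):
        X, y = separable_counts(10)
        outputs = iter(
            [np.asarray(y)]  # perfect at the first resolution
            + [np.arange(X.n_cells) % 3 for _ in range(29)]
        )

        def fake_cluster(adj, r):
            return next(outputs)

        best = louvain_grid_cluster(
            X, list(X.gene_ids), k_neighbors=3, ground_truth=y, cluster_fn=fake_cluster
        )
        assert best["ari"] == 1.0 and best["fms"] == 1.0

    def test_too_many_neighbors_rejected(self):
        X, y = separable_counts(3)
        with pytest.raises(ValueError):
            louvain_grid_cluster(
                X, list(X.gene_ids), k_neighbors=6, ground_truth=y,
                cluster_fn=lambda a, r: np.asarray(y),
            )


def all_genes_selector(X_tr, y_tr, m):
    return list(X_tr.gene_ids)


class TestCrossValidatedEvaluation:
    def test_separable_data_with_all_genes_has_near_zero_error(self):
        X, y = separable_counts(20, seed=1)
        rep = cross_validated_evaluation(X, y, all_genes_selector, [6], K=5, seed=0)
        err = rep.aggregates.query("metric == 'error'").value.iloc[0]
        assert err <= 0.05

    def test_deterministic_report(self):
        X, y = separable_counts(10, seed=2)
        a = cross_validated_evaluation(X, y, all_genes_selector, [6], K=5, seed=4)
        b = cross_validated_evaluation(X, y, all_genes_selector, [6], K=5, seed=4)
        pd.testing.assert_frame_equal(a.points, b.points)

    def test_held_out_cells_never_reach_the_selector(self):
        X, y = separable_counts(10, seed=3)
        folds_seen = []

        def recording_selector(X_tr, y_tr, m):
            folds_seen.append(set(X_tr.cell_ids))
            return ["g0", "g1"]

        cross_validated_evaluation(X, y, recording_selector, [2], K=5, seed=9)
        from rankcorr import make_folds

        folds = make_folds(X.n_cells, K=5, seed=9)
        for f, seen in enumerate(folds_seen, start=1):
            held_out = {X.cell_ids[i] for i in np.flatnonzero(folds.test_mask(f))}
            assert seen.isdisjoint(held_out)

    def test_poisoned_held_out_fold_changes_nothing(self):
        # a fake perfect gene planted only in held-out rows must not alter
        # the markers selected on the training folds
        X, y = separable_counts(10, seed=5)
        from rankcorr import make_folds, rank_corr

        folds = make_folds(X.n_cells, K=5, seed=2)
        test_rows = folds.test_mask(1)
        V = X.dense().copy()
        V[test_rows, 5] = 999  # poison an otherwise boring gene
        X_poisoned = CountMatrix(V, gene_ids=X.gene_ids)
        train = ~test_rows
        a = rank_corr(X.subset_cells(train), y[train], s=1.5)
        b = rank_corr(X_poisoned.subset_cells(train), y[train], s=1.5)
        assert a.union == b.union

    def test_missing_class_in_training_split_is_reported(self):
        X, _ = separable_counts(10)
        y_rare = np.zeros(20, dtype=int)
        y_rare[3] = 1  # a singleton class must be absent from some split
        with pytest.raises(ValueError, match="fold"):
            cross_validated_evaluation(X, y_rare, all_genes_selector, [2], K=5, seed=0)


class TestAomRank:
    @staticmethod
    def make_aggregates(rows):
        return pd.DataFrame(rows, columns=["method", "n_markers", "metric", "value"])

    def test_average_of_medians_arithmetic(self):
        rows = [
            ("M", n, metric, v)
            for metric, values in (("ari", (0.5, 0.7, 0.9)), ("ami", (0.3, 0.4, 0.5)))
            for n, v in zip((10, 20, 30), values)
        ]
        out = aom_rank(
            self.make_aggregates(rows),
            marker_ranges=[(0, 40)],
            families={"clustering": ("ari", "ami")},
        )
        assert out.aom.iloc[0] == pytest.approx((0.7 + 0.4) / 2)

    def test_single_metric_single_point(self):
        out = aom_rank(
            self.make_aggregates([("M", 10, "ari", 0.42)]),
            marker_ranges=[(5, 15)],
            families={"clustering": ("ari",)},
        )
        assert out.aom.iloc[0] == pytest.approx(0.42)

    def test_uniformly_better_method_ranks_first_everywhere(self):
        rows = []
        for n in (10, 20, 60, 80):
            rows += [("good", n, "ari", 0.8), ("bad", n, "ari", 0.3)]
        out = aom_rank(
            self.make_aggregates(rows),
            marker_ranges=[(0, 30), (50, 100)],
            families={"clustering": ("ari",)},
        )
        good = out[out.method == "good"]
        assert set(good["rank"]) == {1}
        assert set(out[out.method == "bad"]["rank"]) == {2}

    def test_error_metrics_flip_before_averaging(self):
        rows = [("A", 10, "error", 0.1), ("B", 10, "error", 0.4)]
        out = aom_rank(
            self.make_aggregates(rows),
            marker_ranges=[(0, 20)],
            families={"classification": ("error",)},
        )
        a = out[out.method == "A"]
        assert a.aom.iloc[0] == pytest.approx(0.9)
        assert a["rank"].iloc[0] == 1

    def test_ties_share_the_minimum_rank(self):
        rows = [("A", 10, "ari", 0.5), ("B", 10, "ari", 0.5), ("C", 10, "ari", 0.1)]
        out = aom_rank(
            self.make_aggregates(rows),
            marker_ranges=[(0, 20)],
            families={"clustering": ("ari",)},
        ).set_index("method")
        assert out.loc["A", "rank"] == out.loc["B", "rank"] == 1
        assert out.loc["C", "rank"] == 3

    def test_empty_range_names_method_and_range(self):
        rows = [("M", 100, "ari", 0.5)]
        with pytest.raises(ValueError, match="M.*range"):
            aom_rank(
                self.make_aggregates(rows),
                marker_ranges=[(0, 50)],
                families={"clustering": ("ari",)},
            )
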