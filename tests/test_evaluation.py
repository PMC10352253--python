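import numpy as np
import pytest

from qmorph import (
    BenchmarkGrid,
    PrecomputedSVM,
    SyntheticSpec,
    crossval_precomputed,
    default_extraction_grid,
    default_selection_grid,
    generate_dataset,
    holdout_split,
    run_benchmark,
    top_n,
)
from qmorph.evaluation import (
    ALGORITHMS,
    BenchmarkRow,
    rows_to_frame,
    svm_fit_precomputed,
    svm_predict,
)


def block_kernel(y, eps: float = 0.02):
    """Within-class similarity ~1, cross-class ~0 (strictly PSD)."""
    K = np.where(np.equal.outer(y, y), 1.0 - eps, 0.0)
    return K + eps * np.eye(len(y))


class TestPrecomputedSVM:
    def test_two_point_toy(self):
        K = np.array([[1.0, 0.1], [0.1, 1.0]])
        y = np.array([0, 1])
        model = svm_fit_precomputed(K, y)
        assert svm_predict(model, K).tolist() == [0, 1]

    def test_block_perfect_14_classes_zero_training_error(self, rng):
        y = np.repeat(np.arange(14), 4)
        K = block_kernel(y)
        model = svm_fit_precomputed(K, y)
        assert (svm_predict(model, K) == y).all()

    def test_predict_training_block_consistency(self, rng):
        y = rng.integers(0, 3, size=30)
        X = rng.normal(size=(30, 4))
        K = X @ X.T + 30 * np.eye(30)
        model = svm_fit_precomputed(K, y)
        assert np.array_equal(model.predict(K), model.predict(K))

    def test_all_zero_rows_fall_to_lowest_class(self):
        y = np.array([5, 5, 9, 9])
        model = svm_fit_precomputed(block_kernel(y), y)
        pred = svm_predict(model, np.zeros((2, 4)))
        # zero similarity everywhere: the decision is the documented
        # deterministic tie-break, the lowest class index
        assert (pred == 5).all()

    def test_permutation_invariance(self, rng):
        y = rng.integers(0, 3, size=24)
        K = block_kernel(y, eps=0.1)
        perm = rng.permutation(24)
        pred = svm_predict(svm_fit_precomputed(K, y), K)
        pred_p = svm_predict(
            svm_fit_precomputed(K[np.ix_(perm, perm)], y[perm]), K[np.ix_(perm, perm)]
        )
        assert np.array_equal(pred[perm], pred_p)

    def test_errors(self):
        with pytest.raises(ValueError, match="square"):
            svm_fit_precomputed(np.ones((3, 2)), np.array([0, 1, 0]))
        with pytest.raises(ValueError, match="2 classes"):
            svm_fit_precomputed(np.eye(3), np.zeros(3))
        model = svm_fit_precomputed(np.eye(4), np.array([0, 0, 1, 1]))
        with pytest.raises(ValueError, match="columns"):
            model.predict(np.ones((2, 3)))

    def test_pair_models_store_duals(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        model = svm_fit_precomputed(block_kernel(y), y)
        assert len(model.pairs_) == 3
        for pm in model.pairs_:
            assert pm.dual_coef.size == pm.support.size
            assert np.isfinite(pm.intercept)


class TestHoldoutSplit:
    def test_80_20_stratified_sizes(self, rng):
        y = np.repeat(np.arange(5), 20)
        train, test = holdout_split(y, 0.8, seed=0)
        assert len(train) == 80 and len(test) == 20
        for cls in range(5):
            assert (y[train] == cls).sum() == 16

    def test_union_and_disjointness(self, rng):
        y = rng.integers(0, 3, size=53)
        train, test = holdout_split(y, 0.8, seed=1)
        assert len(np.intersect1d(train, test)) == 0
        assert np.array_equal(np.sort(np.concatenate([train, test])), np.arange(53))

    def test_same_seed_identical(self, rng):
        y = rng.integers(0, 4, size=40)
        assert all(
            np.array_equal(a, b)
            for a, b in zip(holdout_split(y, seed=7), holdout_split(y, seed=7))
        )

    def test_singleton_class_kept_in_train(self):
        y = np.array([0] * 10 + [1])
        with pytest.warns(UserWarning, match="single member"):
            train, test = holdout_split(y, 0.8, seed=0)
        assert 10 in train

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            holdout_split(np.array([0, 1]), 1.2)


class TestCrossval:
    def test_five_folds_and_mean(self, rng):
        y = np.repeat(np.arange(3), 10)
        report = crossval_precomputed(block_kernel(y), y, k=5, seed=0)
        assert len(report.fold_scores) == 5
        assert report.mean == pytest.approx(np.mean(report.fold_scores), abs=1e-12)
        assert report.ci95_halfwidth == pytest.approx(
            1.96 * report.std / np.sqrt(5), abs=1e-12
        )

    def test_block_perfect_kernel_scores_one(self):
        y = np.repeat(np.arange(4), 10)
        report = crossval_precomputed(block_kernel(y), y, k=5, seed=0)
        assert report.mean == 1.0 and report.std == 0.0

    def test_k_exceeding_class_count_rejected(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="smallest class"):
            crossval_precomputed(np.eye(6), y, k=5)


class TestBenchmarkGrid:
    def test_extraction_grid_cardinality(self):
        grid = default_extraction_grid()
        assert grid.n_cells_per_algorithm() == 11 * 14 == 154
        assert grid.n_cells_per_algorithm() >= 150

    def test_selection_grid_cardinality(self):
        grid = default_selection_grid()
        assert grid.n_cells_per_algorithm() == 11 * 3

    def test_one_cell_grid(self, small_table):
        grid = BenchmarkGrid(
            rescalers=["quantile_uniform"],
            reducers=[("selection", "decision_tree", 5)],
            algorithms=["q_kernel_zz"],
            seed=1,
        )
        rows = run_benchmark(small_table, grid)
        assert len(rows) == 1
        assert rows[0].status == "ok"
        assert rows[0].cv_mean is not None and rows[0].cv_mean > 0.5
        assert rows[0].n_qubits == 5

    def test_failed_cells_are_recorded_not_fatal(self, small_table):
        """Box-Cox requires strictly positive data, so planting a negative
        cell makes that rescaler's cells fail; they must be recorded as error
        rows without aborting the healthy minmax cells."""
        frame = small_table.frame.copy()
        frame.iloc[0, frame.columns.get_loc("F01")] = -1.0
        table = small_table.with_frame(frame)
        grid = BenchmarkGrid(
            rescalers=["boxcox", "minmax"],
            reducers=[("selection", "decision_tree", 3)],
            algorithms=["SVM_linear"],
            seed=1,
        )
        rows = run_benchmark(table, grid)
        by_resc = {r.rescaling: r for r in rows}
        assert by_resc["boxcox"].status == "error"
        assert "positive" in by_resc["boxcox"].error
        assert by_resc["minmax"].status == "ok"

    def test_empty_grid_rejected(self, small_table):
        with pytest.raises(ValueError, match="empty"):
            run_benchmark(small_table, BenchmarkGrid(rescalers=[]))

    def test_deterministic_under_root_seed(self, small_table):
        grid = BenchmarkGrid(
            rescalers=["minmax"],
            reducers=[("selection", "random_forest", 4)],
            algorithms=["SVM_rbf", "q_kernel_8"],
            seed=3,
        )
        a = rows_to_frame(run_benchmark(small_table, grid))
        b = rows_to_frame(run_benchmark(small_table, grid))
        assert a.equals(b)

    def test_qubit_cap_enforced(self, small_table):
        grid = BenchmarkGrid(
            rescalers=["minmax"],
            reducers=[("selection", "decision_tree", 12)],
            algorithms=["q_kernel_zz"],
            seed=0,
        )
        rows = run_benchmark(small_table, grid)
        assert rows[0].status == "error"
        assert "cap" in rows[0].error

    def test_algorithm_names_cover_table_rows(self):
        assert set(ALGORITHMS) == {
            "SVM_linear", "SVM_rbf", "SVM_poly", "SVM_sigmoid",
            "q_kernel_zz", "q_kernel_default", "q_kernel_8", "q_kernel_9",
            "q_kernel_10", "q_kernel_11", "q_kernel_12", "q_kernel_training",
        }


class TestTopN:
    def _rows(self):
        mk = lambda resc, mean, std: BenchmarkRow(resc, "dt_top5", "SVM_rbf",
                                                  cv_mean=mean, cv_std=std)
        return [mk("a", 0.91, 0.01), mk("b", 0.93, 0.02), mk("c", 0.91, 0.005)]

    def test_orders_by_mean_then_std(self):
        rows = top_n(self._rows(), 3)
        assert [r.rescaling for r in rows] == ["b", "c", "a"]

    def test_n_larger_than_rows(self):
        assert len(top_n(self._rows(), 10)) == 3

    def test_single_best(self):
        assert top_n(self._rows(), 1)[0].cv_mean == 0.93

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            top_n([], 5)


class TestSampleSizeTrend:
    def test_cv_mean_non_decreasing_within_one_std(self):
        """More synthetic data should not hurt: across growing sample sizes
        the CV mean of the fixed pipeline (rank-uniform rescale, tree top-5,
        zz fidelity kernel) never drops by more than one fold standard
        deviation.  3-fold CV on the full table keeps every class usable at
        the smallest size."""
        from qmorph import (FeatureMapSpec, Rescaler, encode_labels,
                            kernel_matrix, select_top_k, tree_importances)

        means, stds = [], []
        for n in (100, 250, 500, 1000):
            table = generate_dataset(SyntheticSpec(n_neurons=n, seed=1))
            X = Rescaler("quantile_uniform").fit_transform(table.features)
            y, _ = encode_labels(table.labels)
            keep = select_top_k(tree_importances(X, y, "decision_tree", seed=1), 5)
            K = kernel_matrix(X[:, keep], FeatureMapSpec(n_qubits=5, encoding="zz"))
            report = crossval_precomputed(K, y, k=3, seed=1)
            means.append(report.mean)
            stds.append(report.std)
        for i in range(1, len(means)):
            assert means[i] >= means[i - 1] - max(stds[i], stds[i - 1], 1e-9)
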