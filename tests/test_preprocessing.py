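import math

import numpy as np
import pytest
from scipy import stats

from qmorph import (
    RESCALER_METHODS,
    Rescaler,
    RescalerSpec,
    apply_filters,
    apply_rescaler,
    drop_incomplete_rows,
    drop_zero_soma,
    encode_labels,
    fit_rescaler,
    mahalanobis_distances,
    mahalanobis_filter,
)
from qmorph.preprocessing import decode_labels
from qmorph.synthetic import SOMA_SURFACE, M_TYPES


class TestRowFilters:
    def test_no_missing_is_identity(self, small_table):
        out, report = drop_incomplete_rows(small_table)
        assert out.frame.equals(small_table.frame)
        assert report.removed_missing == []

    def test_missing_row_count(self, rng):
        import pandas as pd

        n = 100
        frame = pd.DataFrame({
            "neuron_id": [str(i) for i in range(n)],
            "label": ["a"] * n,
            SOMA_SURFACE: np.ones(n),
            "F01": np.ones(n),
        })
        rows = rng.choice(n, size=7, replace=False)
        frame.loc[rows, "F01"] = np.nan
        from qmorph import MorphometryTable

        out, report = drop_incomplete_rows(MorphometryTable(frame))
        assert out.n_rows == 93
        assert sorted(report.removed_missing) == sorted(rows.tolist())

    def test_zero_soma_strict_equality(self, small_table):
        frame = small_table.frame.copy()
        frame.iloc[0, frame.columns.get_loc(SOMA_SURFACE)] = 1e-12
        frame.iloc[1, frame.columns.get_loc(SOMA_SURFACE)] = 0.0
        out, report = drop_zero_soma(small_table.with_frame(frame))
        assert report.removed_zero_soma == [1]
        assert 0 in out.frame.index  # 1e-12 is kept

    def test_zero_soma_missing_column_errors(self, small_table):
        frame = small_table.frame.drop(columns=[SOMA_SURFACE])
        from qmorph import MorphometryTable

        with pytest.raises(ValueError, match=SOMA_SURFACE):
            drop_zero_soma(MorphometryTable(frame))

    def test_filters_recover_ground_truth(self, artifact_table):
        """Missing and zero-soma filters remove exactly the planted rows, and
        the Mahalanobis filter removes every planted outlier."""
        table, _ = artifact_table
        art = table.artifacts
        filtered, report = apply_filters(table)
        assert sorted(report.removed_missing) == art.missing_rows.tolist()
        assert sorted(report.removed_zero_soma) == art.zero_soma_rows.tolist()
        assert set(art.outlier_rows.tolist()) <= set(report.removed_mahalanobis)
        union = (set(report.removed_missing) | set(report.removed_zero_soma)
                 | set(report.removed_mahalanobis))
        assert report.rows_out == report.rows_in - len(union)
        assert filtered.n_rows == report.rows_out

    def test_report_serialises(self, artifact_table):
        import json

        _, report = apply_filters(artifact_table[0])
        parsed = json.loads(json.dumps(report.to_dict()))
        assert parsed["rows_in"] == 300


class TestMahalanobis:
    def test_distance_is_squared_euclidean_for_whitened_data(self, rng):
        X = rng.normal(size=(500, 4))
        X = X - X.mean(axis=0)
        L = np.linalg.cholesky(np.linalg.inv(np.cov(X, rowvar=False)))
        Xw = X @ L  # exactly unit sample covariance, zero mean
        d2 = mahalanobis_distances(Xw, shrinkage=False)
        # np.cov uses ddof=1, so distances scale by (n-1)/n relative to ||x||^2
        assert np.allclose(d2, np.sum(Xw**2, axis=1), rtol=1e-6)

    def test_row_at_mean_always_kept(self, rng):
        X = rng.normal(size=(100, 3))
        # make row 0 the exact column mean: x0 = mean(others) => x0 = mean(all)
        X[0] = X[1:].mean(axis=0)
        kept, _ = mahalanobis_filter(X, alpha=0.025)
        assert 0 in kept

    def test_planted_8sigma_outliers_removed(self, rng):
        X = rng.normal(size=(2000, 10))
        X[:25] += 8.0 * np.sign(rng.normal(size=(25, 10)))
        kept, report = mahalanobis_filter(X, alpha=0.025)
        removed = set(report.removed_mahalanobis)
        assert all(i in removed for i in range(25))
        clean_removed = len(removed - set(range(25)))
        assert clean_removed / 1975 <= 0.05

    def test_singular_without_shrinkage_advises_shrinkage(self, rng):
        X = rng.normal(size=(10, 43))
        with pytest.raises(ValueError, match="shrinkage"):
            mahalanobis_filter(X, shrinkage=False)


class TestRescalers:
    def test_standard_two_point_closed_form(self):
        X = np.array([[0.0], [2.0]])
        spec = fit_rescaler(X, "standard")
        assert spec.params["mean"][0] == 1.0 and spec.params["sd"][0] == 1.0
        assert np.allclose(apply_rescaler(spec, X).ravel(), [-1.0, 1.0])

    def test_standard_invariant_on_training_data(self, small_table):
        Z = Rescaler("standard").fit_transform(small_table.features)
        assert np.abs(Z.mean(axis=0)).max() < 1e-9
        assert np.abs(Z.var(axis=0) - 1.0).max() < 1e-9

    def test_minmax_endpoints(self, rng):
        X = rng.uniform(5, 9, size=(30, 3))
        Z = Rescaler("minmax").fit_transform(X)
        assert np.allclose(Z.min(axis=0), 0.0) and np.allclose(Z.max(axis=0), 1.0)

    def test_logistic_at_zero(self):
        spec = fit_rescaler(np.zeros((3, 1)), "logistic")
        assert apply_rescaler(spec, np.zeros((1, 1)))[0, 0] == 0.5

    def test_robust_printed_formula_and_median_variant(self, rng):
        X = rng.normal(size=(200, 2))
        spec = fit_rescaler(X, "robust")
        q1 = np.percentile(X, 25, axis=0)
        q3 = np.percentile(X, 75, axis=0)
        assert np.allclose(apply_rescaler(spec, X), (X - q1) / (q3 - q1))
        spec_m = fit_rescaler(X, "robust", center="median")
        med = np.median(X, axis=0)
        assert np.allclose(apply_rescaler(spec_m, X), (X - med) / (q3 - q1))

    def test_l2norm_rows_unit(self, rng):
        X = rng.normal(size=(50, 5))
        Z = Rescaler("l2norm").fit_transform(X)
        assert np.allclose(np.linalg.norm(Z, axis=1), 1.0, atol=1e-12)

    def test_boxcox_log_branch_at_e(self):
        spec = RescalerSpec("boxcox", {"lmbda": np.array([0.0])}, n_features=1)
        out = apply_rescaler(spec, np.array([[math.e]]))
        assert np.isclose(out[0, 0], 1.0)

    def test_boxcox_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="positive"):
            fit_rescaler(np.array([[1.0], [0.0]]), "boxcox")

    def test_yeojohnson_mle_near_one_on_gaussian(self, rng):
        """On symmetric standard-normal data the Yeo-Johnson MLE should find
        lambda ~ 1 (no transformation); cross-checked against an independent
        log-likelihood grid."""
        x = rng.normal(size=(5000, 1))
        spec = fit_rescaler(x, "yeojohnson")
        lam = spec.params["lmbda"][0]
        assert abs(lam - 1.0) < 0.15
        grid = np.linspace(lam - 0.5, lam + 0.5, 201)
        llf = [stats.yeojohnson_llf(g, x.ravel()) for g in grid]
        assert abs(grid[int(np.argmax(llf))] - lam) < 0.02

    def test_lognormal_cdf_and_domain(self):
        spec = fit_rescaler(np.array([[1.0], [2.0]]), "lognormal")
        out = apply_rescaler(spec, np.array([[1.0], [0.0]]))
        assert np.isclose(out[0, 0], 0.5)  # Phi(ln 1) = 0.5
        assert out[1, 0] == 0.0  # limit at x = 0
        with pytest.raises(ValueError, match="x >= 0"):
            apply_rescaler(spec, np.array([[-1.0]]))

    def test_quantile_normal_median_maps_to_zero(self, rng):
        X = rng.lognormal(size=(501, 1))
        spec = fit_rescaler(X, "quantile_normal")
        out = apply_rescaler(spec, np.median(X, axis=0, keepdims=True))
        assert abs(out[0, 0]) < 1e-9

    def test_quantile_uniform_range_and_ks(self, small_table):
        X = small_table.features
        Z = Rescaler("quantile_uniform").fit_transform(X)
        assert Z.min() >= 0.0 and Z.max() <= 1.0
        n = len(Z)
        for j in (0, 7, 21):
            ks = stats.kstest(Z[:, j], "uniform").statistic
            assert ks < 2.0 / math.sqrt(n)

    def test_fit_transform_separation(self, rng):
        """Transforming held-out data must use training statistics only, so
        out-of-range test values land outside [0, 1] under minmax."""
        train, test = rng.uniform(0, 1, (50, 1)), np.array([[2.0]])
        r = Rescaler("minmax").fit(train)
        assert r.transform(test)[0, 0] > 1.0

    def test_constant_feature_passes_through_with_warning(self):
        X = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        with pytest.warns(UserWarning, match="constant"):
            spec = fit_rescaler(X, "standard")
        Z = apply_rescaler(spec, X)
        assert np.allclose(Z[:, 0], 3.0)  # untouched
        assert abs(Z[:, 1].mean()) < 1e-12

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            fit_rescaler(np.ones((3, 1)), "zscore")

    @pytest.mark.parametrize("method", [m for m in RESCALER_METHODS if m != "boxcox"])
    def test_all_methods_run_on_synthetic_table(self, small_table, method):
        Z = Rescaler(method).fit_transform(small_table.features)
        assert Z.shape == small_table.features.shape
        assert np.isfinite(Z).all()

    def test_boxcox_on_positive_table(self, small_table):
        Z = Rescaler("boxcox").fit_transform(small_table.features)
        assert np.isfinite(Z).all()

    def test_spec_yaml_roundtrip(self, rng):
        X = rng.uniform(1, 2, size=(40, 3))
        spec = fit_rescaler(X, "quantile_uniform")
        restored = RescalerSpec.from_yaml(spec.to_yaml())
        assert np.allclose(apply_rescaler(restored, X), apply_rescaler(spec, X))


class TestLabelEncoding:
    def test_lexicographic(self):
        codes, classes = encode_labels(["basket", "astrocyte", "basket"])
        assert classes == ["astrocyte", "basket"]
        assert codes.tolist() == [1, 0, 1]

    def test_roundtrip(self, small_table):
        codes, classes = encode_labels(small_table.labels)
        assert (decode_labels(codes, classes) == small_table.labels).all()

    def test_fourteen_mtypes_map_to_0_13(self):
        codes, classes = encode_labels(list(M_TYPES))
        assert sorted(codes.tolist()) == list(range(14))
        assert classes == sorted(M_TYPES)
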