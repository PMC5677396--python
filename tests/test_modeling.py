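import numpy as np
import pandas as pd
import pytest

from soilhsi import (
    SVMConfig,
    fit_plsr,
    fit_svm,
    fuse_features,
    pca_lda_explore,
    regression_metrics,
    stratified_split,
)

FAST_SVM = SVMConfig(log2c=(-3, 9, 4), log2g=(-9, 3, 4), cv_folds=3)


class TestStratifiedSplit:
    def test_study_design_counts(self):
        labels = np.repeat([1, 2, 3], [84, 57, 42])
        split = stratified_split(labels, seed=0)
        cal_labels = labels[split.calibration_idx]
        pred_labels = labels[split.prediction_idx]
        assert [np.sum(cal_labels == c) for c in (1, 2, 3)] == [56, 38, 28]
        assert [np.sum(pred_labels == c) for c in (1, 2, 3)] == [28, 19, 14]

    def test_pooled_unstratified_counts(self):
        split = stratified_split(None, n_samples=183, seed=0)
        assert (len(split.calibration_idx), len(split.prediction_idx)) == (122, 61)

    def test_minimal_class(self):
        split = stratified_split(np.array([1, 1, 1]), seed=0)
        assert (len(split.calibration_idx), len(split.prediction_idx)) == (2, 1)

    def test_partition_properties(self, rng):
        labels = rng.integers(1, 4, size=60)
        split = stratified_split(labels, seed=3)
        union = np.sort(np.concatenate([split.calibration_idx, split.prediction_idx]))
        np.testing.assert_array_equal(union, np.arange(60))

    def test_deterministic_per_seed(self):
        labels = np.repeat([1, 2, 3], 10)
        a = stratified_split(labels, seed=5)
        b = stratified_split(labels, seed=5)
        np.testing.assert_array_equal(a.calibration_idx, b.calibration_idx)
        c = stratified_split(labels, seed=6)
        assert not np.array_equal(a.calibration_idx, c.calibration_idx)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError, match="ratio"):
            stratified_split(np.array([1, 1, 1, 2, 2, 2]), ratio=1.5)


def _separable_problem(rng, n=30):
    y = np.repeat([1, 2, 3], n)
    X = np.vstack([rng.normal(loc=10 * c, scale=0.1, size=(n, 4)) for c in (1, 2, 3)])
    return X, y


class TestSvm:
    def test_separable_classes_perfectly_classified(self, rng):
        X, y = _separable_problem(rng)
        split = stratified_split(y, seed=0)
        _, rep_cal, rep_pred = fit_svm(
            X[split.calibration_idx], y[split.calibration_idx],
            X[split.prediction_idx], y[split.prediction_idx], FAST_SVM,
        )
        assert rep_cal.overall_accuracy == 1.0
        assert rep_pred.overall_accuracy == 1.0

    def test_permuted_labels_score_at_chance(self, rng):
        X, y = _separable_problem(rng, n=20)
        accs = []
        for seed in range(10):
            local = np.random.default_rng(seed)
            yp = local.permutation(y)
            split = stratified_split(yp, seed=seed)
            _, _, rep = fit_svm(
                X[split.calibration_idx], yp[split.calibration_idx],
                X[split.prediction_idx], yp[split.prediction_idx], FAST_SVM,
            )
            accs.append(rep.overall_accuracy)
        assert abs(np.mean(accs) - 1 / 3) < 0.15

    def test_confusion_trace_identity_and_row_sums(self, rng):
        X, y = _separable_problem(rng, n=10)
        y_noisy = y.copy()
        y_noisy[::7] = ((y_noisy[::7]) % 3) + 1  # inject label noise
        split = stratified_split(y_noisy, seed=1)
        _, rep_cal, rep_pred = fit_svm(
            X[split.calibration_idx], y_noisy[split.calibration_idx],
            X[split.prediction_idx], y_noisy[split.prediction_idx], FAST_SVM,
        )
        for rep, idx in ((rep_cal, split.calibration_idx), (rep_pred, split.prediction_idx)):
            assert rep.overall_accuracy == pytest.approx(
                np.trace(rep.confusion) / rep.confusion.sum()
            )
            counts = [np.sum(y_noisy[idx] == c) for c in rep.classes]
            np.testing.assert_array_equal(rep.confusion.sum(axis=1), counts)

    def test_single_class_calibration_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            fit_svm(X, np.ones(10), config=FAST_SVM)

    def test_grid_search_invariant_to_column_order(self, rng):
        X, y = _separable_problem(rng, n=12)
        X += rng.normal(scale=5.0, size=X.shape)
        split = stratified_split(y, seed=2)
        perm = rng.permutation(X.shape[1])
        reports = []
        for Xv in (X, X[:, perm]):
            _, _, rep = fit_svm(
                Xv[split.calibration_idx], y[split.calibration_idx],
                Xv[split.prediction_idx], y[split.prediction_idx], FAST_SVM,
            )
            reports.append(rep)
        assert reports[0].c == reports[1].c and reports[0].g == reports[1].g
        assert reports[0].overall_accuracy == reports[1].overall_accuracy


class TestFuseFeatures:
    def _blocks(self, rng):
        ids = [f"S{i}" for i in range(5)]
        spec = pd.DataFrame(rng.normal(size=(5, 7)), index=ids,
                            columns=[f"wl_{i}" for i in range(7)])
        tex = pd.DataFrame(rng.normal(size=(5, 28)), index=ids,
                           columns=[f"t_{i}" for i in range(28)])
        return spec, tex

    def test_seven_plus_28_gives_35_columns(self, rng):
        spec, tex = self._blocks(rng)
        fused = fuse_features(spec, tex)
        assert fused.shape == (5, 35)
        assert list(fused.columns[:7]) == list(spec.columns)

    def test_empty_texture_block_is_identity(self, rng):
        spec, tex = self._blocks(rng)
        pd.testing.assert_frame_equal(fuse_features(spec, tex.iloc[:, :0]), spec)

    def test_shuffled_rows_rejected(self, rng):
        spec, tex = self._blocks(rng)
        with pytest.raises(ValueError, match="sample ids"):
            fuse_features(spec, tex.iloc[::-1])


class TestPcaLda:
    def test_separable_classes_full_accuracy(self, rng):
        X, y = _separable_problem(rng, n=15)
        _, accuracy, _ = pca_lda_explore(X, y, n_pcs=3)
        assert accuracy == 1.0

    def test_score_covariance_diagonal(self, rng):
        from sklearn.decomposition import PCA

        X = rng.normal(size=(30, 6)) @ rng.normal(size=(6, 6))
        scores = PCA(n_components=4).fit_transform(X)
        cov = np.cov(scores.T)
        np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0.0, atol=1e-8)

    def test_variance_ratio_sums_to_one_at_full_rank(self, rng):
        X = rng.normal(size=(20, 5))
        _, _, evr = pca_lda_explore(X, np.repeat([1, 2], 10), n_pcs=5)
        assert np.sum(evr) == pytest.approx(1.0)

    def test_too_many_pcs_rejected(self, rng):
        with pytest.raises(ValueError, match="n_pcs"):
            pca_lda_explore(rng.normal(size=(4, 6)), np.array([1, 1, 2, 2]), n_pcs=4)


class TestPlsr:
    def test_exact_linear_relation_recovered(self, rng):
        latent = rng.normal(size=(30, 3))
        X = latent @ rng.normal(size=(3, 12))
        y = latent @ np.array([1.0, -0.5, 2.0])
        model = fit_plsr(X, y, max_components=6)
        assert model.n_components <= 3 + 1
        np.testing.assert_allclose(model.predict(X), y, atol=1e-8)

    def test_truncated_coefficients_match_refits(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        from soilhsi.modeling import _pls_truncated_coefs

        X = rng.normal(size=(25, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=25)
        coefs = _pls_truncated_coefs(X, y, 5)
        for k, (B, b0) in enumerate(coefs, start=1):
            ref = PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(
                X @ B + b0, ref.predict(X).ravel(), atol=1e-8
            )

    def test_pure_noise_has_no_predictive_power(self):
        r2s = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 15))
            y = rng.normal(size=40)
            model = fit_plsr(X[:30], y[:30], max_components=8)
            r2s.append(regression_metrics(y[30:], model.predict(X[30:])).r2)
        assert np.mean(r2s) < 0.3

    def test_rank_one_predictors_match_univariate_regression(self, rng):
        direction = rng.normal(size=6)
        t = rng.normal(size=20)
        X = np.outer(t, direction)
        y = 2.0 * t + 1.0 + rng.normal(scale=0.05, size=20)
        with pytest.warns(UserWarning, match="clipped"):
            model = fit_plsr(X, y, max_components=5)
        slope, intercept = np.polyfit(t, y, 1)
        np.testing.assert_allclose(model.predict(X), slope * t + intercept, atol=1e-8)


class TestRegressionMetrics:
    @staticmethod
    def vectors_with(sd, rmsep, mean=0.16):
        d = sd / np.sqrt(2)
        y_true = np.array([mean - d, mean + d])
        y_pred = y_true + np.array([-rmsep, rmsep])
        return y_true, y_pred

    def test_rpd_is_sd_over_rmsep(self):
        y_true, y_pred = self.vectors_with(sd=0.042, rmsep=0.0166)
        m = regression_metrics(y_true, y_pred)
        assert m.rmsep == pytest.approx(0.0166)
        assert m.rpd == pytest.approx(0.042 / 0.0166)
        assert round(m.rpd, 1) == 2.5

    def test_second_worked_example(self):
        y_true, y_pred = self.vectors_with(sd=0.037, rmsep=0.0176)
        assert round(regression_metrics(y_true, y_pred).rpd, 1) == 2.1

    def test_perfect_prediction_sentinels(self, rng):
        y = rng.normal(size=10)
        m = regression_metrics(y, y)
        assert m.rmsep == 0.0 and m.r2 == 1.0 and np.isinf(m.rpd)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regression_metrics(np.ones(5), np.zeros(5))

    def test_r2_is_one_minus_ss_ratio(self, rng):
        y = rng.normal(size=20)
        yhat = y + rng.normal(scale=0.5, size=20)
        m = regression_metrics(y, yhat)
        expected = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
        assert m.r2 == pytest.approx(expected)
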