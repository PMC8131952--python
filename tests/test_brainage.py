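import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import surfage as sa
from surfage.brainage import fit_linear_age_model


def rank_one_age_features(n=80, units=40, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(18, 88, n)
    loadings = rng.normal(0, 1, units)
    X = np.outer(ages - ages.mean(), loadings)
    if noise:
        X = X + rng.normal(0, noise, X.shape)
    return X, ages


class TestPcaScores:
    def test_rank_one_recovery(self):
        X, ages = rank_one_age_features()
        s = sa.pca_scores(X, 1)[:, 0]
        r = np.corrcoef(s, ages)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 6))
        k = 6
        center = X.mean(axis=0)
        _, _, vt = np.linalg.svd(X - center, full_matrices=False)
        scores = sa.pca_scores(X, k)
        # scores through any orthonormal basis reproduce centred data norms
        assert np.linalg.norm(scores) == pytest.approx(np.linalg.norm(X - center))

    def test_holdout_projection_matches_sklearn(self):
        """Held-out scores equal projection onto fit-derived axes (sklearn
        PCA as the independent oracle)."""
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 15))
        fit_rows = np.arange(20)
        ours = sa.pca_scores(X, 4, fit_rows=fit_rows)
        ref = PCA(n_components=4, svd_solver="full").fit(X[fit_rows])
        theirs = ref.transform(X)
        # align per-component signs before comparing
        for j in range(4):
            sgn = np.sign(ours[:, j] @ theirs[:, j])
            assert np.abs(ours[:, j] - sgn * theirs[:, j]).max() < 1e-8

    def test_k_beyond_rank_bound_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 10))
        with pytest.raises(ValueError):
            sa.pca_scores(X, 5)

    def test_deterministic_sign_convention(self):
        X = np.random.default_rng(3).normal(size=(30, 8))
        s1 = sa.pca_scores(X, 3)
        s2 = sa.pca_scores(X.copy(), 3)
        assert np.array_equal(s1, s2)


class TestPredictionMetrics:
    def test_perfect_prediction(self):
        ages = np.linspace(20, 80, 10)
        m = sa.prediction_metrics(ages.copy(), ages)
        assert m["rmse"] == 0.0 and m["mae"] == 0.0

    def test_constant_offset(self):
        ages = np.linspace(20, 80, 10)
        m = sa.prediction_metrics(ages + 2.0, ages)
        assert m["rmse"] == pytest.approx(2.0)
        assert m["mae"] == pytest.approx(2.0)
        assert m["corr"] == pytest.approx(1.0)

    def test_constant_prediction_flagged(self):
        m = sa.prediction_metrics(np.array([30.0, 30.0]), np.array([20.0, 40.0]))
        assert m["rmse"] == pytest.approx(10.0)
        assert m["mae"] == pytest.approx(10.0)
        assert np.isnan(m["corr"])


class TestAdjustedR2:
    def test_perfect_fit_gives_one(self):
        X, ages = rank_one_age_features()
        assert sa.adjusted_r2(X[:, :3], ages) == pytest.approx(1.0)

    def test_intercept_only_convention(self):
        assert sa.adjusted_r2(np.empty((30, 0)), np.linspace(20, 80, 30)) == 0.0

    def test_closed_form_penalty(self):
        """adj R^2 = 1 - (1-R^2)(n-1)/(n-k-1); with R^2 = 0.5, n = 101,
        k = 20 this is 0.375."""
        rng = np.random.default_rng(7)
        n, k = 101, 20
        X = rng.normal(size=(n, k))
        y = rng.normal(size=n)
        _, fitted, resid = fit_linear_age_model(X, y)
        r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        expected = 1 - (1 - r2) * (n - 1) / (n - k - 1)
        assert sa.adjusted_r2(X, y) == pytest.approx(expected, abs=1e-12)
        assert 1 - (1 - 0.5) * 100 / 80 == pytest.approx(0.375)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=60)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert sa.adjusted_r2(X, y) == pytest.approx(ref.rsquared_adj, abs=1e-12)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            sa.adjusted_r2(np.random.rand(5, 4), np.random.rand(5))


class TestCvPredictAge:
    def test_intercept_only_null_model(self):
        rng = np.random.default_rng(9)
        ages = rng.uniform(18, 88, 100)
        X = rng.normal(size=(100, 20))
        res = sa.cv_predict_age(X, ages, ks=[0], folds=10, repetitions=2, seed=0)
        # every prediction is its training fold's mean age
        assert res.metrics.loc[0, "rmse"] == pytest.approx(ages.std(ddof=0), rel=0.05)

    def test_noiseless_rank_one_is_perfectly_predicted(self):
        X, ages = rank_one_age_features(noise=0.0)
        res = sa.cv_predict_age(X, ages, ks=[1], folds=10, repetitions=1, seed=0)
        assert res.metrics.loc[1, "rmse"] < 1e-6

    def test_k_beyond_fold_rank_rejected(self):
        X, ages = rank_one_age_features(n=20, units=50, noise=0.5)
        with pytest.raises(ValueError):
            sa.cv_predict_age(X, ages, ks=[19], folds=10)

    def test_subject_order_invariance(self):
        """Fold assignment is keyed to subject ids, so permuting rows leaves
        the metrics unchanged."""
        rng = np.random.default_rng(10)
        ages = rng.uniform(18, 88, 60)
        X = np.outer(ages, rng.normal(0, 1, 30)) + rng.normal(0, 20, (60, 30))
        ids = np.array([f"s{i:03d}" for i in range(60)])
        res1 = sa.cv_predict_age(X, ages, ks=[2, 5], folds=5, repetitions=2,
                                 seed=3, subject_ids=ids)
        perm = rng.permutation(60)
        res2 = sa.cv_predict_age(X[perm], ages[perm], ks=[2, 5], folds=5,
                                 repetitions=2, seed=3, subject_ids=ids[perm])
        assert np.allclose(res1.metrics[["rmse", "mae", "corr"]],
                           res2.metrics[["rmse", "mae", "corr"]])

    def test_repetition_stability(self, default_cohort):
        """Metric spread across repetitions is small relative to the value
        (the motivation for treating few repetitions as sufficient)."""
        cohort, _ = default_cohort
        res = sa.cv_predict_age(cohort.thickness[:, :500], cohort.ages, ks=[10],
                                folds=10, repetitions=5, seed=1,
                                subject_ids=cohort.subject_ids)
        per_rep = [
            sa.prediction_metrics(res.predicted[r, 0], cohort.ages)["rmse"]
            for r in range(5)
        ]
        assert np.std(per_rep) / np.mean(per_rep) < 0.02

    def test_insample_residuals_orthogonal_to_scores(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(50, 20))
        ages = rng.uniform(18, 88, 50)
        scores = sa.pca_scores(X, 8)
        _, _, resid = fit_linear_age_model(scores, ages)
        assert np.abs(resid @ scores).max() < 1e-9


class TestDelta:
    def test_delta1_sign_convention(self):
        ages = np.linspace(20, 80, 10)
        assert (sa.delta1(ages + 3.0, ages) == 3.0).all()
        assert (sa.delta1(ages.copy(), ages) == 0.0).all()

    def test_delta2_of_collinear_delta1_vanishes(self):
        ages = np.linspace(20, 80, 30)
        d1 = 2.0 * (ages - ages.mean())
        assert np.abs(sa.delta2(d1, ages)).max() < 1e-10

    def test_delta2_fixed_point_when_already_orthogonal(self):
        rng = np.random.default_rng(12)
        ages = rng.uniform(18, 88, 40)
        noise = rng.standard_normal(40)
        d1 = sa.delta2(noise, ages)  # orthogonalize once
        assert np.allclose(sa.delta2(d1, ages), d1, atol=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_delta2_orthogonality_identities(self, seed):
        rng = np.random.default_rng(seed)
        ages = rng.uniform(18, 88, 50)
        d1 = rng.normal(0, 5, 50) - 0.1 * ages
        d2 = sa.delta2(d1, ages)
        assert abs(d2.mean()) < 1e-10
        assert abs(np.corrcoef(d2, ages)[0, 1]) < 1e-10

    def test_cross_validated_delta1_negatively_correlated_with_age(self, default_cohort):
        """Regression to the training mean makes predicted-minus-true age
        decrease with age."""
        cohort, _ = default_cohort
        res = sa.cv_predict_age(cohort.thickness, cohort.ages, ks=[12], folds=10,
                                repetitions=2, seed=2, subject_ids=cohort.subject_ids)
        d1 = sa.delta1(res.mean_predicted(12), cohort.ages)
        assert np.corrcoef(d1, cohort.ages)[0, 1] < 0


class TestDeltaConditionCorrelations:
    def test_identical_vectors_give_unit_correlation(self):
        v = np.random.default_rng(0).normal(size=30)
        mat = sa.delta_condition_correlations({"a": v, "b": v.copy()})
        assert mat.loc["a", "b"] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(1)
        mat = sa.delta_condition_correlations(
            {c: rng.normal(size=40) for c in "abc"}
        )
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        n = 400
        mat = sa.delta_condition_correlations(
            {c: rng.normal(size=n) for c in "ab"}
        )
        assert abs(mat.loc["a", "b"]) < 3 / np.sqrt(n)

    def test_subject_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sa.delta_condition_correlations(
                {"a": np.zeros(10), "b": np.zeros(12)}
            )
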