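import numpy as np
import pytest
from sklearn.linear_model import ElasticNet

from pdxsig.io import SensitivityProfile
from pdxsig.model import (
    ConvergenceError,
    FitConfig,
    PreprocessSpec,
    apply_zscore,
    coordinate_descent_fit,
    cross_validate,
    elastic_net_objective,
    fit_signature,
    kkt_violation,
    lambda_path,
    load_signature,
    predict,
    remove_nonnormal_outputs,
    save_signature,
    soft_threshold,
    zscore_fit_transform,
)

from conftest import make_matrix


@pytest.mark.parametrize(
    "z,gamma,expected",
    [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), (-3.0, 1.0, -2.0), (1.7, 0.0, 1.7)],
)
def test_soft_threshold(z, gamma, expected):
    assert soft_threshold(z, gamma) == expected


def _unit_feature(n=4):
    """A single feature with mean 0 and (1/n) sum z^2 = 1."""
    z = np.array([1.0, 1.0, -1.0, -1.0][:n])
    return z[:, None]


class TestCoordinateDescent:
    def test_single_feature_lasso_closed_form(self):
        """(1/n) z'y = 0.8, alpha = 1, lambda = 0.3 -> beta = S(0.8, 0.3) = 0.5."""
        Z = _unit_feature()
        y = 0.8 * Z[:, 0]
        fit = coordinate_descent_fit(Z, y, alpha=1.0, lam=0.3)
        assert fit.coefs[0] == pytest.approx(0.5, abs=1e-9)
        assert fit.beta0 == pytest.approx(0.0, abs=1e-12)

    def test_single_feature_ridge_limit(self):
        """alpha -> 0 at lambda = 0.2: beta = 0.8 / 1.2."""
        Z = _unit_feature()
        y = 0.8 * Z[:, 0]
        fit = coordinate_descent_fit(Z, y, alpha=1e-12, lam=0.2)
        assert fit.coefs[0] == pytest.approx(0.8 / 1.2, rel=1e-6)

    def test_lambda_max_boundary_gives_null_model(self):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        lam_max = lambda_path(Z, y, alpha=1.0)[0]
        fit = coordinate_descent_fit(Z, y, alpha=1.0, lam=lam_max * (1 + 1e-12))
        assert np.all(fit.coefs == 0.0)
        assert fit.beta0 == pytest.approx(np.mean(y))

    def test_matches_reference_minimizer_on_random_instances(self):
        """Objective within 1e-6 of scikit-learn's solver, 50 instances."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            n, p = int(rng.integers(10, 31)), int(rng.integers(2, 11))
            Z = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            alpha = float(rng.uniform(0.05, 1.0))
            lam = float(rng.uniform(0.01, 0.5))
            fit = coordinate_descent_fit(Z, y, alpha, lam, tol=1e-9)
            ref = ElasticNet(alpha=lam, l1_ratio=alpha, tol=1e-10,
                             max_iter=200_000).fit(Z, y)
            obj_ref, _ = elastic_net_objective(Z, y, ref.intercept_, ref.coef_,
                                               alpha, lam)
            assert fit.objective <= obj_ref + 1e-6
            assert abs(fit.objective - obj_ref) < 1e-6

    def test_kkt_conditions_hold_at_solution(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            Z = rng.standard_normal((25, 8))
            y = Z[:, 0] * 0.5 + rng.standard_normal(25)
            alpha, lam = 0.7, 0.1
            fit = coordinate_descent_fit(Z, y, alpha, lam, tol=1e-8)
            Zc = Z - Z.mean(axis=0)
            yc = y - y.mean()
            assert kkt_violation(Zc, yc, 0.0, fit.coefs, alpha, lam) < 1e-6

    def test_grouping_of_identical_features(self):
        """With alpha < 1 duplicated features share the coefficient."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30)
        Z = np.column_stack([x, x, rng.standard_normal(30)])
        y = 2 * x + rng.standard_normal(30) * 0.1
        fit = coordinate_descent_fit(Z, y, alpha=0.5, lam=0.1, tol=1e-10)
        assert fit.coefs[0] == pytest.approx(fit.coefs[1], abs=1e-6)

    def test_solution_path_continuity(self):
        """Coefficients vary smoothly along a fine lambda grid."""
        rng = np.random.default_rng(4)
        Z = rng.standard_normal((30, 6))
        y = Z @ np.array([1.0, -0.5, 0, 0, 0.3, 0]) + rng.standard_normal(30) * 0.2
        lams = lambda_path(Z, y, alpha=0.8, n_lambda=200, min_ratio=1e-2)
        fits = [coordinate_descent_fit(Z, y, 0.8, lam).coefs for lam in lams]
        diffs = np.abs(np.diff(np.array(fits), axis=0)).max(axis=1)
        # no jump exceeds 10x the neighboring steps (plus an absolute floor)
        for i in range(1, len(diffs) - 1):
            neighbor = max(diffs[i - 1], diffs[i + 1], 1e-4)
            assert diffs[i] <= 10 * neighbor

    def test_nonzero_map_excludes_zeros(self):
        Z = _unit_feature()
        y = 0.8 * Z[:, 0]
        fit = coordinate_descent_fit(Z, y, alpha=1.0, lam=0.9,
                                     feature_ids=["g1"])
        assert fit.beta == {} and fit.n_nonzero == 0

    def test_invalid_penalties_rejected(self):
        Z, y = _unit_feature(), np.zeros(4)
        with pytest.raises(ValueError):
            coordinate_descent_fit(Z, y, alpha=0.0, lam=0.1)
        with pytest.raises(ValueError):
            coordinate_descent_fit(Z, y, alpha=0.5, lam=-0.1)


class TestLambdaPath:
    def test_all_zero_at_grid_start(self):
        rng = np.random.default_rng(5)
        Z = rng.standard_normal((15, 4))
        y = rng.standard_normal(15)
        grid = lambda_path(Z, y, alpha=0.6)
        fit = coordinate_descent_fit(Z, y, 0.6, grid[0] * (1 + 1e-10))
        assert np.all(fit.coefs == 0)

    def test_grid_shape_and_monotonicity(self):
        rng = np.random.default_rng(6)
        Z, y = rng.standard_normal((10, 3)), rng.standard_normal(10)
        grid = lambda_path(Z, y, alpha=1.0, n_lambda=50)
        assert len(grid) == 50 and np.all(np.diff(grid) < 0)

    def test_halving_alpha_doubles_lambda_max(self):
        rng = np.random.default_rng(7)
        Z, y = rng.standard_normal((10, 3)), rng.standard_normal(10)
        assert lambda_path(Z, y, 0.5)[0] == pytest.approx(
            2 * lambda_path(Z, y, 1.0)[0]
        )

    def test_constant_outcome_is_error(self):
        Z = np.random.default_rng(8).standard_normal((10, 3))
        with pytest.raises(ValueError, match="zero variance"):
            lambda_path(Z, np.ones(10), alpha=1.0)


class TestZScore:
    def test_transform_properties_and_idempotence(self, small_matrix):
        Z, params = zscore_fit_transform(small_matrix)
        np.testing.assert_allclose(Z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=1, ddof=1), 1, atol=1e-12)
        np.testing.assert_allclose(apply_zscore(params, small_matrix), Z)

    def test_constant_feature_dropped_with_warning(self):
        vals = np.vstack([np.arange(5.0), np.full(5, 3.0)])
        m = make_matrix(vals)
        with pytest.warns(UserWarning, match="constant"):
            Z, params = zscore_fit_transform(m)
        assert params.feature_ids == ["G1"] and Z.shape == (1, 5)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            zscore_fit_transform(make_matrix([[1.0]]))


class TestOutlierRemoval:
    def test_extreme_value_removed(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(50)
        y[17] = 10 * y.std()
        kept, removed = remove_nonnormal_outputs(y)
        assert list(removed) == [17]
        assert len(kept) == 49

    def test_normal_draws_rarely_removed(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(100)
        _, removed = remove_nonnormal_outputs(y)
        assert len(removed) <= 4  # ~1.5% expected at cutoff 2.5

    def test_constant_outcome_warns_and_keeps_all(self):
        with pytest.warns(UserWarning, match="MAD"):
            kept, removed = remove_nonnormal_outputs(np.ones(10))
        assert len(kept) == 10 and len(removed) == 0

    def test_removal_capped_at_max_fraction(self):
        y = np.concatenate([np.zeros(6), np.full(4, 100.0), [0.001] * 2])
        with pytest.warns(UserWarning):
            kept, removed = remove_nonnormal_outputs(y, max_frac=0.2)
        assert len(removed) <= 2


def _planted_matrix(seed=0, n=60, p=40, k=3, r2=0.8):
    rng = np.random.default_rng(seed)
    vals = rng.normal(8, 1, size=(p, n))
    Z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1,
                                                             keepdims=True)
    betas = np.array([1.0, -0.8, 0.9])[:k]
    s = betas @ Z[:k]
    noise = rng.normal(0, s.std() * np.sqrt((1 - r2) / r2), n)
    return make_matrix(vals), s + noise, [f"G{i + 1}" for i in range(k)]


class TestCrossValidate:
    def test_deterministic_under_seed(self):
        X, y, _ = _planted_matrix()
        cv1 = cross_validate(X, y, alpha_grid=(0.5, 1.0), k=5, seed=3)
        cv2 = cross_validate(X, y, alpha_grid=(0.5, 1.0), k=5, seed=3)
        assert cv1.selected_alpha == cv2.selected_alpha
        assert cv1.selected_lambda == cv2.selected_lambda
        assert cv1.table.equals(cv2.table)

    def test_selection_attains_minimum(self):
        X, y, _ = _planted_matrix(seed=1)
        cv = cross_validate(X, y, alpha_grid=(0.3, 1.0), k=5, seed=0)
        row = cv.table[(cv.table.alpha == cv.selected_alpha)
                       & (cv.table.lam == cv.selected_lambda)]
        assert row.mse.iloc[0] == cv.min_mse()

    def test_needs_enough_samples(self):
        X, y, _ = _planted_matrix(n=10)
        with pytest.raises(ValueError, match="2k"):
            cross_validate(X, y, k=10)


class TestFitSignature:
    def test_recovers_planted_features(self):
        X, y, planted = _planted_matrix(seed=2)
        sig = fit_signature(X, y, FitConfig(seed=0, k_folds=5))
        assert set(planted) <= set(sig.fit.beta)
        assert sig.n_features_selected >= 3
        assert sig.fit.kkt < 1e-5

    def test_bit_reproducible_given_seed(self):
        X, y, _ = _planted_matrix(seed=3)
        a = fit_signature(X, y, FitConfig(seed=4, k_folds=5))
        b = fit_signature(X, y, FitConfig(seed=4, k_folds=5))
        assert a.fit.beta == b.fit.beta
        assert a.selected_lambda == b.selected_lambda

    def test_linc_count_by_biotype(self):
        rng = np.random.default_rng(5)
        n, p = 60, 20
        vals = rng.normal(0, 1, size=(p, n))
        y = vals[0] - vals[p - 1] + rng.normal(0, 0.3, n)
        biotypes = ["coding"] * (p - 1) + ["lincRNA"]
        X = make_matrix(vals, biotypes=biotypes)
        sig = fit_signature(X, y, FitConfig(seed=0, k_folds=5))
        selected = set(sig.fit.beta)
        expected_linc = 1 if f"G{p}" in selected else 0
        assert sig.n_linc_selected == expected_linc

    def test_unscreenable_outcome_is_error(self):
        rng = np.random.default_rng(6)
        X = make_matrix(rng.normal(size=(10, 30)))
        y = rng.normal(size=30)  # independent of X
        spec = PreprocessSpec(alpha_local=1e-9)
        with pytest.raises(ValueError, match="alpha_local"):
            fit_signature(X, y, FitConfig(seed=0, k_folds=5,
                                          preprocess=spec))

    def test_censored_profiles_included_by_default(self):
        X, y, _ = _planted_matrix(seed=7)
        profiles = [
            SensitivityProfile("d", sid, 10.0**yi, censored=(i == 0))
            for i, (sid, yi) in enumerate(zip(X.sample_ids, y))
        ]
        sig_inc = fit_signature(X, profiles, FitConfig(seed=0, k_folds=5))
        assert sig_inc.fit.n in (len(y), len(y) - len(sig_inc.removed_samples))
        cfg_ex = FitConfig(seed=0, k_folds=5, include_censored=False)
        sig_ex = fit_signature(X, profiles, cfg_ex)
        assert sig_ex.fit.n <= sig_inc.fit.n


class TestPredict:
    def _toy_signature(self):
        X, y, _ = _planted_matrix(seed=8)
        return fit_signature(X, y, FitConfig(seed=0, k_folds=5)), X, y

    def test_arithmetic_on_known_coefficients(self):
        sig, X, _ = self._toy_signature()
        # overwrite with a hand signature: beta0 = 1, one feature coef 0.5
        sig.fit.coefs[:] = 0.0
        idx = sig.fit.feature_ids.index("G1")
        sig.fit.coefs[idx] = 0.5
        sig.fit.beta0 = 1.0
        t = sig.transform
        j = t.feature_ids.index("G1")
        vals = np.full((len(X.feature_ids), 1), 0.0)
        vals[X.feature_ids.index("G1"), 0] = t.means[j] + 2 * t.sds[j]
        X_new = make_matrix(vals)
        scores = predict(sig, X_new, standardize="stored")
        assert scores[0] == pytest.approx(1.0 + 0.5 * 2.0)

    def test_all_zero_coefficients_give_constant(self):
        sig, X, _ = self._toy_signature()
        sig.fit.coefs[:] = 0.0
        scores = predict(sig, X)
        np.testing.assert_allclose(scores, sig.fit.beta0)

    def test_training_predictions_track_outcome(self):
        sig, X, y = self._toy_signature()
        scores = predict(sig, X, standardize="stored")
        y_std = (y - sig.y_mean) / sig.y_sd
        r = np.corrcoef(scores, y_std)[0, 1]
        assert r > 0.8

    def test_missing_features_beyond_ten_percent_error(self):
        sig, X, _ = self._toy_signature()
        active = list(sig.fit.beta)
        keep = [f for f in X.feature_ids if f not in active]
        X_missing = X.subset_features(keep)
        if len(active) >= 1:
            with pytest.raises(ValueError, match="absent"):
                predict(sig, X_missing)


def test_signature_serialization_round_trip(tmp_path):
    X, y, _ = _planted_matrix(seed=9)
    sig = fit_signature(X, y, FitConfig(seed=1, k_folds=5))
    save_signature(sig, tmp_path / "sig.json")
    back = load_signature(tmp_path / "sig.json")
    assert back.fit.beta == sig.fit.beta
    assert back.fit.beta0 == sig.fit.beta0
    assert back.selected_alpha == sig.selected_alpha
    assert back.selected_lambda == sig.selected_lambda
    np.testing.assert_array_equal(back.transform.means, sig.transform.means)
    scores_a = predict(sig, X)
    scores_b = predict(back, X)
    np.testing.assert_array_equal(scores_a, scores_b)
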