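"""PLSR correctness against oracles, CV equivalence, screening and splitting."""

import numpy as np
import pytest
from scipy import stats

from leafspec import (
    PLSModel,
    fit_plsr,
    generate_spectra,
    hotelling_screen,
    loo_cv,
    predict,
    split_calibration_test,
)
from leafspec.modeling import predict_deflation


class TestHotellingScreen:
    def test_null_false_flag_rate_matches_alpha(self):
        # Monte-Carlo against the F-threshold: 3-sd binomial band around 0.05
        rng = np.random.default_rng(0)
        X = rng.multivariate_normal(np.zeros(8), np.eye(8), size=5000)
        kept, removed, t2 = hotelling_screen(X, alpha=0.05, n_pc=2)
        frac = len(removed) / 5000
        band = 3 * np.sqrt(0.05 * 0.95 / 5000)
        assert abs(frac - 0.05) < max(band, 0.02)
        assert len(kept) + len(removed) == 5000

    def test_displaced_sample_is_flagged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 10))
        X[7] += 10.0 * X.std(axis=0)  # 10 pooled-sd displacement
        _, removed, t2 = hotelling_screen(X, alpha=0.05, n_pc=2)
        assert 7 in removed
        assert t2[7] == t2.max()

    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            hotelling_screen(np.ones((20, 5)))

    def test_npc_bounds(self, rng):
        X = rng.normal(size=(6, 10))
        with pytest.raises(ValueError, match="n_pc"):
            hotelling_screen(X, n_pc=6)

    def test_ids_are_propagated(self, rng):
        X = rng.normal(size=(30, 5))
        X[3] += 50.0
        ids = [f"s{i}" for i in range(30)]
        kept, removed, _ = hotelling_screen(X, n_pc=2, ids=ids)
        assert "s3" in removed
        assert set(kept) | set(removed) == set(ids)


class TestSplit:
    def test_sizes_at_study_scale(self, small_dataset):
        spectra, table = small_dataset
        split = split_calibration_test(spectra.sample_ids, table, seed=5)
        assert len(split.calibration_ids) == 96
        assert len(split.test_ids) == 24
        assert not set(split.calibration_ids) & set(split.test_ids)
        assert set(split.calibration_ids) | set(split.test_ids) == set(
            spectra.sample_ids
        )
        assert all(p > 0.05 for p in split.p_values.values())

    def test_deterministic_per_seed(self, small_dataset):
        spectra, table = small_dataset
        a = split_calibration_test(spectra.sample_ids, table, seed=3)
        b = split_calibration_test(spectra.sample_ids, table, seed=3)
        assert a.calibration_ids == b.calibration_ids
        assert a.test_ids == b.test_ids

    def test_welch_p_matches_scipy(self, small_dataset):
        spectra, table = small_dataset
        split = split_calibration_test(spectra.sample_ids, table, seed=5)
        y_cal = table.values_for("N", split.calibration_ids)
        y_test = table.values_for("N", split.test_ids)
        expected = stats.ttest_ind(y_cal, y_test, equal_var=False).pvalue
        assert split.p_values["N"] == pytest.approx(expected)

    def test_degenerate_constant_response_accepted(self):
        import pandas as pd

        ids = [f"s{i}" for i in range(20)]
        table = pd.DataFrame({"N": np.ones(20)}, index=ids)
        split = split_calibration_test(ids, table, seed=0)
        assert split.p_values["N"] == 1.0


class TestNIPALS:
    def test_rank_one_single_factor_exactness(self, rng):
        x = rng.normal(size=30)
        c = rng.normal(size=25)
        X = np.outer(x, c)
        model = fit_plsr(X, x, 1)
        np.testing.assert_allclose(predict(model, X), x, rtol=1e-9, atol=1e-12)

    def test_full_rank_linear_recovery(self, rng):
        # noiseless y = X b0 with rank(X) = r: PLS at r components is exact
        n, p, r = 40, 30, 6
        X = rng.normal(size=(n, r)) @ rng.normal(size=(r, p))
        b0 = rng.normal(size=p)
        y = X @ b0
        model = fit_plsr(X, y, r)
        np.testing.assert_allclose(
            predict(model, X), y, rtol=1e-8, atol=1e-8 * np.abs(y).max()
        )

    def test_single_column_equals_least_squares_slope(self, rng):
        x = rng.normal(size=50)
        y = 2.5 * x + rng.normal(size=50)
        model = fit_plsr(x[:, None], y, 1)
        xc, yc = x - x.mean(), y - y.mean()
        slope = (xc @ yc) / (xc @ xc)
        assert model.coef[0] == pytest.approx(slope, rel=1e-10)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(30, 80))
        y = rng.normal(size=30)
        model = fit_plsr(X, y, 8)
        T = model.scores
        for i in range(8):
            for j in range(i + 1, 8):
                bound = 1e-8 * np.linalg.norm(T[:, i]) * np.linalg.norm(T[:, j])
                assert abs(T[:, i] @ T[:, j]) < bound

    def test_training_rmse_non_increasing_in_lv(self, rng):
        from leafspec import rmse

        X = rng.normal(size=(25, 60))
        y = rng.normal(size=25)
        errors = [
            rmse(y, predict(fit_plsr(X, y, a), X)) for a in range(1, 10)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))

    def test_coefficient_and_deflation_forms_agree(self, rng):
        X = rng.normal(size=(20, 40))
        y = rng.normal(size=20)
        model = fit_plsr(X, y, 5)
        Xnew = rng.normal(size=(7, 40))
        a = predict(model, Xnew)
        b = predict_deflation(model, Xnew)
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_matches_sklearn_pls(self, rng):
        # independent cross-check against scikit-learn's PLS regression
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(30, 50))
        y = rng.normal(size=30)
        ours = predict(fit_plsr(X, y, 4), X)
        theirs = PLSRegression(n_components=4, scale=False).fit(X, y).predict(X)
        np.testing.assert_allclose(ours, theirs.ravel(), rtol=1e-6, atol=1e-10)

    def test_centering_identities(self, rng):
        X = rng.normal(size=(15, 20))
        y = rng.normal(size=15)
        model = fit_plsr(X, y, 3)
        # the row of X-means predicts the calibration y-mean
        assert predict(model, model.x_mean[None, :])[0] == pytest.approx(y.mean())

    def test_errors(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(ValueError, match="constant"):
            fit_plsr(X, np.ones(10), 2)
        with pytest.raises(ValueError, match="band count mismatch"):
            predict(fit_plsr(X, rng.normal(size=10), 2), rng.normal(size=(3, 7)))

    def test_rank_exhaustion_names_attainable_maximum(self, rng):
        X = rng.normal(size=(20, 3))  # centred rank 3
        y = rng.normal(size=20)
        with pytest.raises(ValueError, match="attainable maximum is 3"):
            fit_plsr(X, y, 7)


class TestLooCv:
    def test_press_equals_naive_double_loop(self, rng):
        # brute-force oracle: refit from scratch per fold x LV
        n, p, max_lv = 20, 50, 6
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        result = loo_cv(X, y, max_lv)
        press = np.zeros(max_lv)
        for a in range(1, max_lv + 1):
            for i in range(n):
                rows = np.arange(n) != i
                model = fit_plsr(X[rows], y[rows], a)
                press[a - 1] += (predict(model, X[i][None, :])[0] - y[i]) ** 2
        np.testing.assert_allclose(result.press, press, rtol=1e-9)

    def test_press_arithmetic_and_selection(self):
        # PRESS([1,2,4] vs [1,2,3]) = 1; selection takes the argmin
        pred = np.array([1.0, 2.0, 4.0])
        ref = np.array([1.0, 2.0, 3.0])
        assert np.sum((pred - ref) ** 2) == 1.0

    def test_press_invariants(self, rng):
        X = rng.normal(size=(15, 30))
        y = rng.normal(size=15)
        result = loo_cv(X, y, 5)
        n = 15
        # PRESS = n * RMSE_V^2 at the selected LV
        assert result.press[result.selected_lv - 1] == pytest.approx(
            n * result.rmse_cv**2
        )
        assert result.selected_lv == int(np.argmin(result.press)) + 1

    def test_rank_two_data_improves_at_two_components(self, rng):
        n, p = 20, 30
        X = rng.normal(size=(n, 2)) @ rng.normal(size=(2, p))
        y = X @ rng.normal(size=p)
        result = loo_cv(X, y, 3)
        assert result.press[1] < result.press[0]

    def test_transform_factory_refits_per_fold(self, rng):
        # with a supervised transform the factory must see only n-1 samples:
        # spy on the training shapes it receives
        X = rng.normal(size=(12, 20))
        y = rng.normal(size=12)
        seen = []

        def factory(X_tr, y_tr):
            seen.append(X_tr.shape[0])
            return lambda Z: Z - X_tr.mean(axis=0)

        loo_cv(X, y, 3, transform_factory=factory)
        assert seen[:12] == [11] * 12  # one refit per fold
        assert seen[-1] == 12          # final full-set refit


class TestModelSerialisation:
    def test_text_round_trip_is_bit_exact(self, tmp_path, rng):
        X = rng.normal(size=(20, 30))
        y = rng.normal(size=20)
        model = fit_plsr(X, y, 4)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = PLSModel.load(path)
        np.testing.assert_array_equal(loaded.coef, model.coef)
        np.testing.assert_array_equal(loaded.x_mean, model.x_mean)
        assert loaded.intercept == model.intercept
        assert loaded.n_lv == model.n_lv
        np.testing.assert_array_equal(
            predict(loaded, X), predict(model, X)
        )


def test_parameter_recovery_on_synthetic_spectra():
    """With known nutrient noise, test RMSE approaches the injected sd and
    R^2 its analytic value, averaged over seeds."""
    from leafspec import r_squared, rmse
    from leafspec.synthetic import NutrientConfig

    target_r2 = 0.8
    sd = 0.5
    noise_sd = sd * np.sqrt(1 - target_r2)
    r2s, rmses = [], []
    for seed in range(6):
        cfg = NutrientConfig(
            "X", "percent", -100.0, 100.0, 2.0, sd,
            (1.0, 0.4, 0.6, 0.3), noise_sd,
        )
        spectra, table = generate_spectra(200, "adaxial", [cfg], seed=seed)
        split = split_calibration_test(spectra.sample_ids, table, seed=seed)
        X_cal = spectra.subset(split.calibration_ids).reflectance
        X_test = spectra.subset(split.test_ids).reflectance
        y_cal = table.values_for("X", split.calibration_ids)
        y_test = table.values_for("X", split.test_ids)
        cv = loo_cv(X_cal, y_cal, 15)
        model = fit_plsr(X_cal, y_cal, cv.selected_lv)
        yhat = predict(model, X_test)
        r2s.append(r_squared(y_test, yhat))
        rmses.append(rmse(y_test, yhat))
    assert abs(np.mean(r2s) - target_r2) < 0.1
    assert abs(np.mean(rmses) - noise_sd) / noise_sd < 0.15
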