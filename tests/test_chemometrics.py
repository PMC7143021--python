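"""Autoscaling, univariate fits, SIMPLS vs independent oracles, CV, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import libsquant as lq
from libsquant.chemometrics import autoscale_apply, autoscale_fit, autoscale_invert

from _oracles import nipals_pls1_predict, ols_predict
from conftest import amplitude_peak_table, random_regression


class TestAutoscale:
    def test_two_point_column(self):
        scaler = autoscale_fit(np.array([[1.0], [3.0]]))
        Xs = autoscale_apply(scaler, np.array([[1.0], [3.0]]))
        assert Xs[:, 0] == pytest.approx([-0.7071067811865475, 0.7071067811865475])

    def test_fit_apply_zero_mean_unit_sd(self):
        X, _ = random_regression(0, n=63, p=43)
        Xs = autoscale_apply(autoscale_fit(X), X)
        assert np.all(np.abs(Xs.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(Xs.std(axis=0, ddof=1) - 1) < 1e-10)

    def test_round_trip(self):
        X, _ = random_regression(1, n=63, p=43)
        scaler = autoscale_fit(X)
        back = autoscale_invert(scaler, autoscale_apply(scaler, X))
        assert np.allclose(back, X, rtol=1e-12)

    def test_constant_column_named(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        X[:, 2] = 5.0
        with pytest.raises(ValueError, match="variable 2"):
            autoscale_fit(X)


class TestUnivariate:
    def test_exact_line(self):
        res = lq.ols_univariate(np.array([1.0, 2.0, 3.0]), np.array([0.1, 0.2, 0.3]))
        assert res.slope == pytest.approx(0.1)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r == pytest.approx(1.0)
        assert res.rmse == pytest.approx(0.0, abs=1e-12)

    def test_proportional_signal(self):
        x = np.linspace(0, 1, 21)
        res = lq.ols_univariate(x, 0.5 * x)
        assert res.r == pytest.approx(1.0) and res.rmse == pytest.approx(0.0, abs=1e-12)

    def test_independent_noise_matches_direct_formulas(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=200)
        y = rng.permutation(rng.normal(size=200))
        res = lq.ols_univariate(x, y)
        # direct textbook formulas
        r_direct = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        slope = r_direct * y.std() / x.std()
        assert res.r == pytest.approx(r_direct, abs=1e-12)
        assert res.slope == pytest.approx(slope, rel=1e-9)
        assert abs(res.r) < 0.2
        assert res.rmse == pytest.approx(y.std() * np.sqrt(1 - r_direct**2), rel=1e-9)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            lq.ols_univariate(np.ones(5), np.arange(5.0))


class TestSimpls:
    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("A", [1, 2, 4])
    def test_matches_nipals_pls1(self, seed, A):
        X, y = random_regression(seed, n=25, p=9, noise=0.5)
        Xn, _ = random_regression(seed + 100, n=10, p=9)
        model = lq.simpls_fit(X, y, A)
        ours = lq.pls_predict(model, Xn)
        ref = nipals_pls1_predict(X, y, Xn, A)
        assert np.allclose(ours, ref, atol=1e-8)

    def test_matches_sklearn_pls(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_regression(3, n=40, p=7, noise=0.3)
        for A in (1, 3):
            pls = sklearn.PLSRegression(n_components=A, scale=True)
            pls.fit(X, y)
            ours = lq.pls_predict(lq.simpls_fit(X, y, A), X)
            assert np.allclose(ours, pls.predict(X).ravel(), atol=1e-8)

    def test_full_rank_limit_equals_ols(self):
        X, y = random_regression(2, n=30, p=5, noise=1.0)
        model = lq.simpls_fit(X, y, 5)
        assert np.allclose(lq.pls_predict(model, X), ols_predict(X, y, X), atol=1e-8)

    def test_one_factor_fits_exact_linear_mixture(self):
        cal = amplitude_peak_table("acacia", "hfcs55", seed=11)
        model = lq.simpls_fit(cal.intensities, cal.fractions, 1)
        assert np.max(np.abs(model.fitted - cal.fractions)) < 1e-8

    def test_score_orthogonality(self):
        for seed in range(5):
            X, y = random_regression(seed, n=30, p=10, noise=0.4)
            model = lq.simpls_fit(X, y, 5)
            G = model.T.T @ model.T
            off = G - np.diag(np.diag(G))
            assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_b_equals_R_q(self):
        X, y = random_regression(4, n=30, p=8)
        model = lq.simpls_fit(X, y, 3)
        assert np.allclose(model.b, model.R @ model.q, rtol=1e-12)

    def test_invalid_A_rejected(self):
        X, y = random_regression(0, n=10, p=4)
        with pytest.raises(ValueError, match="A must"):
            lq.simpls_fit(X, y, 0)
        with pytest.raises(ValueError, match="A must"):
            lq.simpls_fit(X, y, 5)

    def test_rank_deficiency_reports_achievable_rank(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(12, 2))
        X = np.hstack([base, base @ rng.normal(size=(2, 3))])  # rank 2
        y = X @ rng.normal(size=5) + 0.01 * rng.normal(size=12)
        with pytest.raises(np.linalg.LinAlgError, match="achievable rank"):
            lq.simpls_fit(X, y, 4)


class TestPredict:
    def test_calibration_consistency(self, noisy_rape):
        _, cal, _ = noisy_rape
        model = lq.simpls_fit(cal.intensities, cal.fractions, 3)
        assert np.allclose(lq.pls_predict(model, cal.intensities), model.fitted, rtol=1e-12)

    def test_duplicated_row_duplicated_prediction(self, noisy_rape):
        _, cal, _ = noisy_rape
        model = lq.simpls_fit(cal.intensities, cal.fractions, 3)
        X2 = np.vstack([cal.intensities[4], cal.intensities[4]])
        preds = lq.pls_predict(model, X2)
        assert preds[0] == preds[1]

    def test_column_mismatch_rejected(self, noisy_rape):
        _, cal, _ = noisy_rape
        model = lq.simpls_fit(cal.intensities, cal.fractions, 2)
        with pytest.raises(ValueError, match="columns"):
            lq.pls_predict(model, cal.intensities[:, :10])

    def test_interpolates_unseen_fraction_exactly_when_noiseless(self):
        cal = amplitude_peak_table("acacia", "hfcs55", seed=11)
        model = lq.simpls_fit(cal.intensities, cal.fractions, 1)
        pure = lq.make_endmember_profile("acacia", 11)
        adult = lq.make_endmember_profile("hfcs55", 11)
        x = (lq.mix_profiles(pure, adult, 0.37).amplitudes + 1.0)[None, :]
        assert lq.pls_predict(model, x)[0] == pytest.approx(0.37, abs=1e-6)


class TestKFoldCV:
    def test_noiseless_chooses_one_factor(self):
        cal = amplitude_peak_table("acacia", "hfcs55", seed=11)
        cv = lq.kfold_cv(cal.intensities, cal.fractions, A_max=5, k=10, seed=1)
        assert cv.chosen_A == 1
        assert cv.rmsecv_by_A[0] < 1e-6

    def test_leave_one_out_matches_brute_force(self):
        X, y = random_regression(9, n=6, p=3, noise=0.3)
        cv = lq.kfold_cv(X, y, A_max=2, k=6, seed=0)
        for A in (1, 2):
            errs = []
            for i in range(6):
                keep = np.arange(6) != i
                model = lq.simpls_fit(X[keep], y[keep], A)
                errs.append((lq.pls_predict(model, X[i : i + 1])[0] - y[i]) ** 2)
            assert cv.rmsecv_by_A[A - 1] == pytest.approx(np.sqrt(np.mean(errs)), rel=1e-10)

    def test_seeded_determinism(self, noisy_rape):
        _, cal, _ = noisy_rape
        a = lq.kfold_cv(cal.intensities, cal.fractions, A_max=6, seed=42)
        b = lq.kfold_cv(cal.intensities, cal.fractions, A_max=6, seed=42)
        assert np.array_equal(a.fold_assignments, b.fold_assignments)
        assert np.array_equal(a.rmsecv_by_A, b.rmsecv_by_A)

    def test_folds_partition_near_equal(self, noisy_rape):
        _, cal, _ = noisy_rape
        cv = lq.kfold_cv(cal.intensities, cal.fractions, A_max=3, k=10, seed=0)
        sizes = np.bincount(cv.fold_assignments, minlength=10)
        assert sizes.sum() == 63 and sizes.max() - sizes.min() <= 1

    def test_a_max_capped_with_warning(self):
        X, y = random_regression(1, n=12, p=20, noise=0.2)
        with pytest.warns(UserWarning, match="capped"):
            cv = lq.kfold_cv(X, y, A_max=15, k=4, seed=0)
        assert len(cv.rmsecv_by_A) <= 8  # min train size 9 -> at most 8 factors

    def test_cv_pessimism_on_noisy_data(self):
        """Held-out RMSECV is no better than calibration RMSE, on average."""
        diffs = []
        for seed in range(8):
            X, y = random_regression(seed, n=40, p=10, noise=1.0)
            cv = lq.kfold_cv(X, y, A_max=4, k=10, seed=seed)
            model = lq.simpls_fit(X, y, 4)
            diffs.append(cv.rmsecv_by_A[3] - lq.rmse(model.fitted, y))
        assert np.mean(diffs) > 0


class TestMetrics:
    def test_identical_vectors(self):
        y = np.array([0.1, 0.4, 0.9])
        assert lq.pearson_r(y, y) == pytest.approx(1.0)
        assert lq.rmse(y, y) == 0.0

    def test_constant_offset(self):
        y = np.array([0.1, 0.4, 0.9])
        assert lq.pearson_r(y + 0.1, y) == pytest.approx(1.0)
        assert lq.rmse(y + 0.1, y) == pytest.approx(0.1)

    def test_matches_direct_formulas(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=50), rng.normal(size=50)
        r_direct = ((a - a.mean()) @ (b - b.mean())) / (
            np.sqrt(((a - a.mean()) ** 2).sum()) * np.sqrt(((b - b.mean()) ** 2).sum())
        )
        assert lq.pearson_r(a, b) == pytest.approx(r_direct, abs=1e-12)
        assert lq.rmse(a, b) == pytest.approx(np.sqrt(np.mean((a - b) ** 2)), rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            lq.pearson_r(np.ones(5), np.arange(5.0))


@given(seed=st.integers(0, 10_000), A=st.integers(1, 4))
@settings(max_examples=30, deadline=None)
def test_simpls_nipals_equivalence_property(seed, A):
    """SIMPLS and NIPALS PLS1 predict identically for any factor count."""
    X, y = random_regression(seed, n=20, p=7, noise=0.8)
    model = lq.simpls_fit(X, y, A)
    assert np.allclose(
        lq.pls_predict(model, X), nipals_pls1_predict(X, y, X, A), atol=1e-8
    )
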