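"""NIPALS PLS1, prediction, and cross-validated latent-variable choice."""

import numpy as np
import pytest

from nircal.errors import IncompatibleAxisError
from nircal.io import SpectraSet
from nircal.pls import PLSModel, cross_validate, fit_pls, predict
from nircal.synthetic import SyntheticConfig, default_components, simulate


def _random_problem(seed, n=30, p=12):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(0, 0.1, n)
    return X, y


class TestFitPls:
    def test_single_predictor_equals_ols(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 1))
        y = 2.0 + 3.0 * x[:, 0] + rng.normal(0, 0.5, 40)
        model = fit_pls(x, y, 1)
        xc = x[:, 0] - x[:, 0].mean()
        slope = xc @ (y - y.mean()) / (xc @ xc)
        np.testing.assert_allclose(
            model.predict_matrix(x), y.mean() + slope * xc, atol=1e-10
        )

    def test_orthogonal_columns_full_lvs_equals_ols(self):
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.normal(size=(30, 6)))
        X = Q  # orthonormal columns
        y = X @ rng.normal(size=6) + rng.normal(0, 0.05, 30)
        model = fit_pls(X, y, 6)
        Xc = X - X.mean(axis=0)
        b_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
        np.testing.assert_allclose(model.coefficients, b_ols, atol=1e-8)

    def test_noiseless_full_rank_interpolates(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 8))
        y = X @ rng.normal(size=8)
        model = fit_pls(X, y, 8)
        np.testing.assert_allclose(model.predict_matrix(X), y, atol=1e-8)

    def test_coefficients_reproducible_from_loadings(self):
        X, y = _random_problem(3)
        model = fit_pls(X, y, 5)
        W, P, q = model.weights, model.x_loadings, model.y_loadings
        b = W @ np.linalg.solve(P.T @ W, q)
        np.testing.assert_allclose(model.coefficients, b, atol=1e-8)

    @pytest.mark.parametrize("n_lvs", [1, 5, 10, 15])
    def test_matches_reference_implementation(self, n_lvs):
        """Independent cross-check against scikit-learn's PLSRegression."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 40))
        y = X[:, :5] @ rng.normal(size=5) + rng.normal(0, 0.2, 60)
        model = fit_pls(X, y, n_lvs)
        ref = sklearn_pls.PLSRegression(n_components=n_lvs, scale=False).fit(X, y)
        np.testing.assert_allclose(
            model.predict_matrix(X), ref.predict(X).ravel(), atol=1e-6
        )

    def test_scale_equivariance(self):
        X, y = _random_problem(5)
        m1 = fit_pls(X, y, 4)
        m2 = fit_pls(X, 10.0 * y, 4)
        np.testing.assert_allclose(
            m2.predict_matrix(X), 10.0 * m1.predict_matrix(X), rtol=1e-10
        )

    def test_preconditions(self):
        X, y = _random_problem(6)
        with pytest.raises(ValueError):
            fit_pls(X, y, 0)
        with pytest.raises(ValueError):
            fit_pls(X, y, X.shape[0])  # > n-1
        with pytest.raises(ValueError):
            fit_pls(X, np.ones(X.shape[0]), 2)  # constant y


class TestPredict:
    def _model_and_spectra(self):
        rng = np.random.default_rng(7)
        lam = np.linspace(1000.0, 1100.0, 20)
        X = rng.normal(size=(15, 20))
        y = X[:, 3] + rng.normal(0, 0.1, 15)
        spectra = SpectraSet(lam, X, [f"S{i}" for i in range(15)])
        model = fit_pls(X, y, 3, wavelength_indices=np.arange(20), axis_nm=lam)
        return model, spectra, y

    def test_training_set_reproduces_fitted_values(self):
        model, spectra, _ = self._model_and_spectra()
        np.testing.assert_allclose(
            predict(model, spectra), model.predict_matrix(spectra.absorbance)
        )

    def test_permuted_samples_permute_predictions(self):
        model, spectra, _ = self._model_and_spectra()
        base = predict(model, spectra)
        perm = [10, 3, 7]
        sub = spectra.subset_samples([spectra.sample_ids[i] for i in perm])
        np.testing.assert_allclose(predict(model, sub), base[perm])

    def test_axis_mismatch_rejected(self):
        model, spectra, _ = self._model_and_spectra()
        shifted = SpectraSet(
            spectra.wavelengths_nm + 0.01, spectra.absorbance, spectra.sample_ids
        )
        with pytest.raises(IncompatibleAxisError):
            predict(model, shifted)

    def test_serialization_roundtrip_via_dict(self):
        model, spectra, _ = self._model_and_spectra()
        back = PLSModel.from_dict(model.to_dict())
        np.testing.assert_allclose(predict(back, spectra), predict(model, spectra))


class TestCrossValidate:
    def test_loo_matches_bruteforce_refits(self):
        X, y = _random_problem(8, n=16, p=6)
        cv = cross_validate(X, y, max_lvs=4, folds=16)
        for k in range(1, 5):
            errs = []
            for i in range(16):
                mask = np.arange(16) != i
                model = fit_pls(X[mask], y[mask], k)
                errs.append((model.predict_matrix(X[i]) - y[i]) ** 2)
            np.testing.assert_allclose(
                cv.rmsecv_by_lv[k - 1], np.sqrt(np.mean(errs)), atol=1e-10
            )

    def test_venetian_assignment(self):
        X, y = _random_problem(9, n=23, p=5)
        cv = cross_validate(X, y, max_lvs=2, folds=10)
        np.testing.assert_array_equal(cv.fold_assignment, np.arange(23) % 10)

    def test_chosen_is_argmin(self):
        X, y = _random_problem(10)
        cv = cross_validate(X, y, max_lvs=6, folds=5)
        assert cv.chosen_lvs == int(np.argmin(cv.rmsecv_by_lv)) + 1

    def test_noise_y_prefers_few_lvs(self):
        """With pure-noise y, RMSECV should not reward extra components:
        over repeated draws the high-LV RMSECV exceeds the low-LV one."""
        worse = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(40, 30))
            y = rng.normal(size=40)
            cv = cross_validate(X, y, max_lvs=8, folds=10)
            worse += cv.rmsecv_by_lv[7] >= cv.rmsecv_by_lv[0]
        assert worse >= 15

    def test_dimensionality_recovery_on_clean_components(self):
        cfg = SyntheticConfig(
            n_samples=40,
            components=default_components()[:3],
            scatter_mult_sd=0,
            scatter_tilt_sd=0,
            scatter_curve_sd=0,
            scatter_add_sd=0,
            noise_sd=0,
            assay_noise_sd=0,
            seed=12,
        )
        spectra, refs, _ = simulate(cfg)
        cv = cross_validate(spectra.absorbance, refs.abts, max_lvs=10, folds=10)
        assert cv.chosen_lvs <= 5

    def test_infeasible_max_lvs_reduced(self, caplog):
        X, y = _random_problem(11, n=12, p=30)
        cv = cross_validate(X, y, max_lvs=20, folds=6)
        assert len(cv.rmsecv_by_lv) < 20
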