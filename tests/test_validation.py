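"""Validation metrics: RMSE, R2, slope, Roy's r2m, y-randomization, cR2P."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nircal.errors import DegenerateSpectrumError
from nircal.io import SpectraSet
from nircal.pls import cross_validate, fit_pls
from nircal.published import iter_cr2p_rows
from nircal.validation import (
    EvaluationReport,
    cr2p,
    evaluate_model,
    r2_through_origin,
    r2m,
    r_squared,
    rmse,
    slope,
    y_randomization,
)


class TestBasicMetrics:
    @pytest.mark.parametrize(
        "m,p,expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1, 2, 3], [2, 3, 4], 1.0),
            ([0, 0], [3, -3], 3.0),
        ],
    )
    def test_rmse(self, m, p, expected):
        assert rmse(m, p) == pytest.approx(expected)

    def test_rmse_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])

    def test_perfect_prediction(self):
        m = np.array([1.0, 2.0, 4.0])
        assert r_squared(m, m) == pytest.approx(1.0)
        assert slope(m, m) == pytest.approx(1.0)

    def test_affine_prediction(self):
        m = np.array([1.0, 2.0, 4.0, 5.0])
        p = 2.0 * m + 7.0
        assert r_squared(m, p) == pytest.approx(1.0)
        assert slope(m, p) == pytest.approx(2.0)

    def test_anticorrelation_visible_in_slope_only(self):
        m = np.array([1.0, 2.0, 4.0])
        assert r_squared(m, -m) == pytest.approx(1.0)  # sign-blind
        assert slope(m, -m) == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            r_squared([1, 1, 1], [1, 2, 3])
        with pytest.raises(DegenerateSpectrumError):
            slope([1, 1, 1], [1, 2, 3])


class TestR2m:
    def test_perfect_prediction_gives_one(self):
        m = np.array([1.0, 2.0, 3.0, 5.0])
        assert r2m(m, m) == pytest.approx(1.0)

    def test_zero_radical_case(self):
        # predictions proportional to measured: r2 == r2_0, r2m == r2
        m = np.array([1.0, 2.0, 3.0, 5.0])
        p = 1.3 * m
        assert r2_through_origin(m, p) == pytest.approx(r_squared(m, p), abs=1e-12)
        assert r2m(m, p) == pytest.approx(r_squared(m, p))

    def test_threshold_gate_behaviour(self):
        # a large systematic offset keeps correlation high but wrecks the
        # through-origin fit, pushing r2m below the 0.5 acceptance gate
        m = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        p = m + 30.0
        assert r_squared(m, p) == pytest.approx(1.0)
        assert r2m(m, p) < 0.5

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_r2m_never_exceeds_r2(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=12)
        p = m + rng.normal(0, 0.5, 12)
        if np.ptp(m) == 0 or np.ptp(p) == 0 or np.allclose(p, 0):
            return
        assert r2m(m, p) <= r_squared(m, p) + 1e-12


class TestCr2p:
    @pytest.mark.parametrize(
        "r2_c,r2_rand,expected",
        [(0.836, 0.042, 0.81), (0.917, 0.082, 0.88), (0.5, 0.0, 0.5)],
    )
    def test_examples(self, r2_c, r2_rand, expected):
        assert round(cr2p(r2_c, r2_rand), 2) == pytest.approx(expected)

    def test_reproduces_every_published_table_cell(self):
        """cR2P = sqrt(R2C)*sqrt(R2C - R2rand) must land within 0.005 of
        every printed benchmark cell (30 rows across both tables)."""
        for table, analyte, method, r2c, r2rand, printed in iter_cr2p_rows():
            value = cr2p(r2c, r2rand)
            assert value == pytest.approx(printed, abs=5e-3), (table, analyte, method)

    def test_rand_exceeding_calibration_rejected(self):
        with pytest.raises(ValueError):
            cr2p(0.5, 0.6)


class TestYRandomization:
    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 15))
        y = X[:, 0] + rng.normal(0, 0.2, 30)
        _, perms1 = y_randomization(X, y, 3, n_perm=8, seed=5)
        _, perms2 = y_randomization(X, y, 3, n_perm=8, seed=5)
        np.testing.assert_array_equal(perms1, perms2)

    def test_null_level_far_below_true_fit_on_structured_data(self):
        # low-rank X with a real y-signal: permuting y should destroy most
        # of the calibration fit (the chance level is what cR2P penalizes)
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(75, 5))
        X = scores @ rng.normal(size=(5, 100)) + rng.normal(0, 0.05, (75, 100))
        y = scores[:, 0] + 0.5 * scores[:, 1] + rng.normal(0, 0.3, 75)
        model = fit_pls(X, y, 4)
        from nircal.validation import r_squared

        r2_true = r_squared(y, model.predict_matrix(X))
        mean_r2, perms = y_randomization(X, y, 4, n_perm=15, seed=0)
        assert perms.shape == (15,)
        assert mean_r2 < 0.5 < r2_true

    def test_subset_argument_restricts_columns(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 10))
        y = rng.normal(size=25)
        a, _ = y_randomization(X, y, 2, selected_indices=np.arange(4), n_perm=5, seed=1)
        b, _ = y_randomization(X[:, :4], y, 2, n_perm=5, seed=1)
        assert a == pytest.approx(b)


class TestEvaluateModel:
    def _perfect_fixture(self):
        # rank-3 X with y in its row space: a 3-LV model is exact, while
        # permuted responses cannot be interpolated (so the cR2P gate is
        # meaningful)
        rng = np.random.default_rng(4)
        lam = np.linspace(1000.0, 1100.0, 12)
        scores = rng.normal(size=(20, 3))
        X = scores @ rng.normal(size=(3, 12))
        y = scores @ np.array([1.0, -0.5, 0.25])  # noiseless, exactly linear
        spectra = SpectraSet(lam, X, [f"S{i}" for i in range(20)])
        cal = spectra.subset_samples([f"S{i}" for i in range(14)])
        pred = spectra.subset_samples([f"S{i}" for i in range(14, 20)])
        model = fit_pls(X[:14], y[:14], 3, wavelength_indices=np.arange(12), axis_nm=lam)
        cv = cross_validate(X[:14], y[:14], max_lvs=6, folds=7)
        return model, cal, y[:14], pred, y[14:], cv

    def test_perfect_noiseless_report(self):
        model, cal, y_cal, pred, y_pred, cv = self._perfect_fixture()
        report = evaluate_model(
            model, cal, y_cal, pred, y_pred, cv, analyte="abts", method="full_pls"
        )
        assert report.r2_c == pytest.approx(1.0)
        assert report.r2_p == pytest.approx(1.0)
        assert report.rmsec == pytest.approx(0.0, abs=1e-8)
        assert report.rmsep == pytest.approx(0.0, abs=1e-8)
        assert report.gates["r2m_pass"] and report.gates["cr2p_pass"]

    def test_report_roundtrip(self):
        model, cal, y_cal, pred, y_pred, cv = self._perfect_fixture()
        report = evaluate_model(model, cal, y_cal, pred, y_pred, cv)
        back = EvaluationReport.from_dict(report.to_dict())
        assert back == report

    def test_overlapping_sets_rejected(self):
        model, cal, y_cal, pred, y_pred, cv = self._perfect_fixture()
        with pytest.raises(ValueError):
            evaluate_model(model, cal, y_cal, cal, y_cal, cv)

    def test_metrics_invariant_to_sample_order(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=20)
        p = m + rng.normal(0, 0.3, 20)
        perm = rng.permutation(20)
        assert rmse(m, p) == pytest.approx(rmse(m[perm], p[perm]))
        assert r_squared(m, p) == pytest.approx(r_squared(m[perm], p[perm]))
        assert r2m(m, p) == pytest.approx(r2m(m[perm], p[perm]))
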