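"""Calibration regression: direct inversion, piecewise quadratic, linear."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from papeors import (
    PiecewiseQuadModel,
    PiecewiseQuadraticRegressor,
    SpecificRotationParams,
    concentration_from_specific_rotation,
    fit_linear,
    fit_piecewise_quadratic,
    predict_concentration,
    predict_linear,
    remove_outliers,
)
from papeors.concentration import NegativePredictionWarning, SERUM_THETA_T


class TestSpecificRotationInversion:
    def test_zero_rotation_zero_concentration(self):
        params = SpecificRotationParams(specific_rotation=1.2)
        assert concentration_from_specific_rotation(0.0, params, 0.002) == 0.0

    def test_arithmetic_oracle(self):
        """c * [theta] * l = theta, so ([theta]=2, l=0.5, theta=1) gives c=1."""
        params = SpecificRotationParams(specific_rotation=2.0)
        assert concentration_from_specific_rotation(1.0, params, 0.5) == pytest.approx(1.0)

    def test_doubling_path_length_halves_concentration(self):
        params = SpecificRotationParams(specific_rotation=1.5)
        c1 = concentration_from_specific_rotation(0.6, params, 0.001)
        c2 = concentration_from_specific_rotation(0.6, params, 0.002)
        assert c2 == pytest.approx(c1 / 2.0, rel=1e-12)

    def test_zero_divisor_rejected(self):
        params = SpecificRotationParams(specific_rotation=0.0)
        with pytest.raises(ValueError, match="nonzero"):
            concentration_from_specific_rotation(0.5, params, 0.002)


class TestRemoveOutliers:
    @staticmethod
    def _quadratic_data(n=20, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        theta = np.linspace(0.2, 1.4, n)
        conc = 50.0 * theta**2 + 150.0 * theta + 30.0
        if noise:
            conc = conc + rng.normal(0, noise, n)
        return theta, conc

    def test_clean_data_nothing_removed(self):
        theta, conc = self._quadratic_data()
        kept_t, kept_c, removed = remove_outliers(theta, conc)
        assert removed == []
        assert kept_t.size == theta.size

    def test_planted_gross_outlier_found(self):
        theta, conc = self._quadratic_data(noise=1.0)
        conc[7] += 400.0
        _, _, removed = remove_outliers(theta, conc)
        assert removed == [7]

    def test_cap_of_three_removals(self):
        """Five planted outliers but only the configured cap is removed."""
        theta, conc = self._quadratic_data(n=30, noise=1.0)
        planted = [3, 9, 15, 21, 27]
        conc[planted] += np.array([500.0, 620.0, 540.0, 700.0, 580.0])
        _, _, removed = remove_outliers(theta, conc, max_removed=3)
        assert len(removed) == 3
        assert set(removed) <= set(planted)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="6"):
            remove_outliers([0.1, 0.2, 0.3], [1.0, 2.0, 3.0])

    def test_deterministic(self):
        theta, conc = self._quadratic_data(noise=5.0, seed=3)
        first = remove_outliers(theta, conc)
        second = remove_outliers(theta, conc)
        np.testing.assert_array_equal(first[0], second[0])
        assert first[2] == second[2]


class TestPiecewiseQuadratic:
    COEFFS = dict(a1=40.0, b1=180.0, k1=25.0, a2=-30.0, b2=420.0, k2=-60.0)

    @classmethod
    def _data(cls, theta_t=0.88, n=40):
        theta = np.linspace(0.1, 1.5, n)
        c = cls.COEFFS
        lower = theta <= theta_t
        conc = np.where(
            lower,
            c["a1"] * theta**2 + c["b1"] * theta + c["k1"],
            c["a2"] * theta**2 + c["b2"] * theta + c["k2"],
        )
        return theta, conc

    def test_exact_recovery_of_planted_coefficients(self):
        theta, conc = self._data()
        model = fit_piecewise_quadratic(theta, conc, theta_t=0.88)
        for name, value in self.COEFFS.items():
            assert getattr(model, name) == pytest.approx(value, abs=1e-8)
        assert model.theta_t == 0.88

    def test_all_zero_concentrations_zero_coefficients(self):
        theta = np.linspace(0.1, 1.5, 20)
        model = fit_piecewise_quadratic(theta, np.zeros(20), theta_t=0.8)
        for name in ("a1", "b1", "k1", "a2", "b2", "k2"):
            assert getattr(model, name) == pytest.approx(0.0, abs=1e-10)

    def test_serum_thresholds_per_polarization(self):
        """The serum defaults near the 200 mg/dl rotation are selectable."""
        assert SERUM_THETA_T == {"V": 0.88, "P": 0.98, "R": 0.822}
        theta, conc = self._data(theta_t=SERUM_THETA_T["R"])
        model = fit_piecewise_quadratic(theta, conc, theta_t=SERUM_THETA_T["R"])
        assert model.theta_t == 0.822

    def test_auto_threshold_finds_changepoint(self):
        """Auto search lands within one grid step of the true discontinuity."""
        theta, conc = self._data(theta_t=0.88)
        model = fit_piecewise_quadratic(theta, conc, theta_t="auto")
        step = np.max(np.diff(np.unique(theta)))
        assert abs(model.theta_t - 0.88) <= step

    def test_sparse_segment_rejected_with_name(self):
        theta = np.linspace(0.1, 0.5, 10)
        conc = theta * 100
        with pytest.raises(ValueError, match="upper segment"):
            fit_piecewise_quadratic(theta, conc, theta_t=0.9)

    def test_fit_predict_round_trip_exact(self):
        theta, conc = self._data()
        model = fit_piecewise_quadratic(theta, conc, theta_t=0.88)
        predicted = predict_concentration(model, theta)
        np.testing.assert_allclose(predicted, conc, atol=1e-6)

    def test_sklearn_estimator_interface(self):
        from sklearn.base import clone

        theta, conc = self._data()
        est = PiecewiseQuadraticRegressor(theta_t=0.88)
        est.fit(theta[:, None], conc)
        assert hasattr(est, "theta_t_")
        assert est.score(theta[:, None], conc) == pytest.approx(1.0)
        cloned = clone(est)
        assert cloned.get_params()["theta_t"] == 0.88


class TestPredictConcentration:
    def test_constant_branch(self):
        model = PiecewiseQuadModel(a1=0, b1=0, k1=100.0, a2=0, b2=0, k2=50.0,
                                   theta_t=0.88)
        assert predict_concentration(model, 0.5) == 100.0

    def test_threshold_belongs_to_lower_branch(self):
        model = PiecewiseQuadModel(a1=0, b1=0, k1=100.0, a2=0, b2=0, k2=50.0,
                                   theta_t=0.88)
        assert predict_concentration(model, 0.88) == 100.0
        assert predict_concentration(model, 0.88 + 1e-12) == 50.0

    def test_negative_prediction_floored_with_warning(self):
        model = PiecewiseQuadModel(a1=0, b1=0, k1=-5.0, a2=0, b2=0, k2=50.0,
                                   theta_t=0.88)
        with pytest.warns(NegativePredictionWarning):
            assert predict_concentration(model, 0.1) == 0.0

    def test_non_finite_rotation_rejected(self):
        model = PiecewiseQuadModel(a1=1, b1=1, k1=1, a2=1, b2=1, k2=1, theta_t=0.88)
        with pytest.raises(ValueError, match="finite"):
            predict_concentration(model, np.nan)

    @given(theta=st.floats(min_value=0.0, max_value=1.5))
    def test_finite_for_finite_rotation(self, theta):
        model = PiecewiseQuadModel(a1=40, b1=180, k1=25, a2=-30, b2=420, k2=-60,
                                   theta_t=0.88)
        assert np.isfinite(predict_concentration(model, theta))


class TestFitLinear:
    def test_exact_line(self):
        theta = np.linspace(0.0, 1.0, 10)
        model = fit_linear(theta, 2.0 * theta + 1.0)
        assert model.slope == pytest.approx(2.0, abs=1e-12)
        assert model.intercept == pytest.approx(1.0, abs=1e-12)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_zero_slope_zero_r2(self):
        theta = np.linspace(0.0, 1.0, 10)
        model = fit_linear(theta, np.full(10, 5.0))
        assert model.slope == 0.0
        assert model.r_squared == 0.0

    def test_noisy_slope_within_three_standard_errors(self):
        rng = np.random.default_rng(11)
        theta = np.linspace(0.0, 1.0, 30)
        conc = 2.8 * theta + 0.4 + rng.normal(0, 0.05, 30)
        from scipy import stats

        result = stats.linregress(theta, conc)
        model = fit_linear(theta, conc)
        assert abs(model.slope - 2.8) <= 3.0 * result.stderr

    def test_identical_rotations_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_linear([0.5, 0.5, 0.5], [1.0, 2.0, 3.0])

    def test_predict_linear(self):
        model = fit_linear([0.0, 1.0], [1.0, 3.0])
        assert predict_linear(model, 2.0) == pytest.approx(5.0)
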