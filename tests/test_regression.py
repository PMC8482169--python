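"""OLS fitting, driving-time equations and the operating recommendation."""

import numpy as np
import pandas as pd
import pytest

from opstress import (
    HRV_TIME_COEFFS,
    MSE_TIME_COEFFS,
    acceptable_operation,
    fit_ols,
    generate_study_dataset,
    predict_driving_time_hrv,
    predict_driving_time_mse,
    sessions_to_frame,
)
from opstress.regression import SingularDesignError

from oracles import normal_equations_ols


def random_design(rng, n=40, p=3):
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"x{i}" for i in range(p)])
    beta = rng.uniform(-3, 3, p)
    y = X.to_numpy() @ beta + rng.uniform(-5, 5) + rng.standard_normal(n)
    return y, X


class TestFitOLS:
    def test_noiseless_data_recovered_exactly(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 2)), columns=["a", "b"])
        y = 3.0 * X["a"] - 1.5 * X["b"] + 7.0
        fit = fit_ols(y, X)
        assert fit.params["const"] == pytest.approx(7.0, abs=1e-9)
        assert fit.params["a"] == pytest.approx(3.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y, X = random_design(rng, n=rng.integers(20, 80), p=rng.integers(1, 5))
        fit = fit_ols(y, X)
        beta, se, r2, adj = normal_equations_ols(y, X.to_numpy())
        est = np.concatenate([[fit.params["const"]], fit.params[X.columns].to_numpy()])
        np.testing.assert_allclose(est, beta, rtol=1e-8)
        np.testing.assert_allclose(
            np.concatenate([[fit.bse["const"]], fit.bse[X.columns].to_numpy()]), se, rtol=1e-8
        )
        assert fit.r_squared == pytest.approx(r2, rel=1e-10)
        assert fit.adj_r_squared == pytest.approx(adj, rel=1e-10)
        assert fit.adj_r_squared <= fit.r_squared

    def test_t_equals_estimate_over_se(self, rng):
        y, X = random_design(rng)
        fit = fit_ols(y, X)
        np.testing.assert_allclose(fit.tvalues, fit.params / fit.bse, rtol=1e-12)

    def test_vif_of_orthogonal_predictors_is_one(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame(
            {
                "c1": np.cos(2 * np.pi * t / n),
                "s1": np.sin(2 * np.pi * t / n),
                "c2": np.cos(4 * np.pi * t / n),
            }
        )
        y = X.sum(axis=1) + np.random.default_rng(0).standard_normal(n)
        fit = fit_ols(y, X)
        np.testing.assert_allclose(fit.vif, 1.0, atol=1e-10)
        assert (fit.vif >= 1 - 1e-12).all()

    def test_rank_deficient_design_names_columns(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 2)), columns=["a", "b"])
        X["sum"] = X["a"] + X["b"]
        with pytest.raises(SingularDesignError, match="sum"):
            fit_ols(rng.standard_normal(30), X)

    def test_constant_column_rejected(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(20), "flat": np.full(20, 2.0)})
        with pytest.raises(SingularDesignError, match="flat"):
            fit_ols(rng.standard_normal(20), X)


class TestDrivingTimeEquations:
    def test_worked_example_value(self):
        # –24.5×2 – 0.35×742.0 – 10.7×131.7 + 2115 = 397.11
        assert predict_driving_time_hrv(2, 742.0, 131.7) == pytest.approx(397.1, abs=0.05)

    def test_intercepts(self):
        assert predict_driving_time_hrv(0, 0, 0) == 2115.0
        assert predict_driving_time_mse(0, 0, 0) == 1823.0

    def test_hand_evaluated_mse_model(self):
        expected = 10.5 * 10 - 0.259 * 800 - 10.3 * 130 + 1823
        assert predict_driving_time_mse(10, 800, 130) == pytest.approx(expected)

    def test_monotonicities(self):
        base = predict_driving_time_hrv(2, 742.0, 131.7)
        assert predict_driving_time_hrv(3, 742.0, 131.7) < base  # stress shortens
        assert predict_driving_time_mse(11, 800, 130) > predict_driving_time_mse(10, 800, 130)

    def test_table_preset_differs_only_in_precision(self):
        pub = HRV_TIME_COEFFS["published"]
        tab = HRV_TIME_COEFFS["table"]
        assert pub.slopes == tab.slopes[:1] + pub.slopes[1:]
        assert abs(pub.intercept - tab.intercept) < 1.0
        assert abs(MSE_TIME_COEFFS["published"].intercept - MSE_TIME_COEFFS["table"].intercept) < 1.0

    def test_parameter_recovery_from_generator(self):
        """Mean refit coefficients over replicates sit within 3 empirical SEs."""
        truth = np.array([2115.0, -24.5, -0.35, -10.7])
        estimates = []
        for seed in range(120):
            df = sessions_to_frame(generate_study_dataset(n_sessions=42, seed=seed))
            beta, _, _, _ = normal_equations_ols(
                df["driving_time"], df[["lf_hf", "rri_ms", "msdv_z"]].to_numpy()
            )
            estimates.append(beta)
        estimates = np.asarray(estimates)
        emp_se = estimates.std(axis=0, ddof=1)
        assert np.all(np.abs(estimates.mean(axis=0) - truth) < 3 * emp_se)


class TestRecommendation:
    def test_published_inversion_reproduces_worked_example(self):
        rec = acceptable_operation(rri_ms=742.0, msdv_z=131.7)
        assert rec.allowable_aw == pytest.approx(2 / 0.0329 - 1.82, rel=1e-12)
        assert rec.allowable_aw == pytest.approx(59.0, abs=0.1)
        assert rec.predicted_driving_time == pytest.approx(397.1, abs=0.1)
        assert rec.predicted_speed_ms == pytest.approx(1.01, abs=0.01)
        assert rec.predicted_speed_kmh == pytest.approx(3.63, abs=0.01)

    def test_algebraic_inversion_of_the_fitted_line(self):
        rec = acceptable_operation(
            rri_ms=742.0, msdv_z=131.7, lfhf_aw_intercept=1.817, inversion_mode="algebraic"
        )
        assert rec.allowable_aw == pytest.approx((2 - 1.817) / 0.0329, rel=1e-12)
        # the two inversions disagree by an order of magnitude
        assert rec.allowable_aw < 10 < acceptable_operation(742.0, 131.7).allowable_aw

    def test_speed_times_time_equals_course_length(self):
        rec = acceptable_operation(rri_ms=700, msdv_z=120, course_length_m=250)
        assert rec.predicted_speed_ms * rec.predicted_driving_time == pytest.approx(250.0)

    def test_out_of_domain_time_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            acceptable_operation(rri_ms=5000.0, msdv_z=200.0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            acceptable_operation(rri_ms=742.0, msdv_z=131.7, lfhf_aw_slope=0.0)
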