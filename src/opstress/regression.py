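"""Driving-time regression models and the acceptable-stress recommendation.

Two fixed linear models relate the per-lap driving time of a tracked
construction machine to operator state and ride vibration:

    time_HRV = −24.5·(LF/HF) − 0.350·RRI − 10.7·MSDVz + 2115
    time_MSE =  10.5·MSE     − 0.259·RRI − 10.3·MSDVz + 1823

(driving time in s, RRI in ms, MSDVz the vertical motion-sickness dose,
MSE the entropy complexity index). ``fit_ols`` refits models of this shape
from data, reporting coefficient SEs, t and p values, per-predictor
variance inflation factors, R², adjusted R² and the overall F test.

The operating recommendation inverts a fitted stress–vibration line
LF/HF = slope·Aw + intercept at a target stress level (LF/HF = 2, the
conventional acceptable level for seated work) to get an allowable
vibration magnitude, then evaluates the HRV driving-time model at the
target stress to get the per-lap time and the implied travel speed.

Two inversion modes are provided because the published worked example
evaluates ``Aw = target/slope − intercept``, which is not the algebraic
inverse of the fitted line (that would be ``(target − intercept)/slope``).
``as_published`` reproduces the printed numbers; ``algebraic`` is the
mathematically consistent inversion. The two differ materially (≈59 vs
≈5.6 m/s² at the default line), so the mode is an explicit argument.

Two coefficient presets ship for each driving-time model: the rounded
coefficients printed with the worked example (``"published"``) and the
full-precision table estimates (``"table"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "RegressionFit",
    "DrivingTimeCoefficients",
    "HRV_TIME_COEFFS",
    "MSE_TIME_COEFFS",
    "OperatingRecommendation",
    "fit_ols",
    "predict_driving_time_hrv",
    "predict_driving_time_mse",
    "acceptable_operation",
]


@dataclass(frozen=True)
class DrivingTimeCoefficients:
    """Slopes (in predictor order) and intercept of a driving-time model."""

    slopes: tuple[float, ...]
    intercept: float
    predictors: tuple[str, ...]

    def predict(self, *values: float) -> float:
        if len(values) != len(self.slopes):
            raise ValueError(f"expected {len(self.slopes)} predictors {self.predictors}")
        return float(np.dot(self.slopes, values) + self.intercept)


#: HRV driving-time model: predictors (LF/HF, RRI ms, MSDVz)
HRV_TIME_COEFFS = {
    "published": DrivingTimeCoefficients((-24.5, -0.35, -10.7), 2115.0, ("lf_hf", "rri_ms", "msdv_z")),
    "table": DrivingTimeCoefficients((-24.5, -0.350, -10.7), 2115.6, ("lf_hf", "rri_ms", "msdv_z")),
}

#: MSE driving-time model: predictors (MSE complexity, RRI ms, MSDVz)
MSE_TIME_COEFFS = {
    "published": DrivingTimeCoefficients((10.5, -0.259, -10.3), 1823.0, ("mse", "rri_ms", "msdv_z")),
    "table": DrivingTimeCoefficients((10.5, -0.259, -10.3), 1823.3, ("mse", "rri_ms", "msdv_z")),
}


@dataclass
class RegressionFit:
    params: pd.Series  # coefficient estimates incl. intercept ("const")
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    vif: pd.Series  # per predictor (no intercept entry)
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_pvalue: float
    nobs: int

    def summary_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "t": self.tvalues, "p": self.pvalues}
        )
        df["vif"] = self.vif.reindex(df.index)
        return df


class SingularDesignError(ValueError):
    pass


def fit_ols(y, X: pd.DataFrame) -> RegressionFit:
    """Ordinary least squares with an intercept, VIF and fit diagnostics.

    ``X`` holds one column per predictor (no constant column). Raises
    ``SingularDesignError`` naming the offending columns when the design is
    rank-deficient.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    if y.size <= X.shape[1] + 1:
        raise ValueError("need more observations than parameters")
    constant = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if constant:
        raise SingularDesignError(f"constant predictor column(s): {constant}")
    design = sm.add_constant(X, has_constant="raise")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        bad = _dependent_columns(X)
        raise SingularDesignError(f"rank-deficient design; linearly dependent column(s): {bad}")
    res = sm.OLS(y, design).fit()
    xv = design.to_numpy()
    vif = pd.Series(
        [variance_inflation_factor(xv, i + 1) for i in range(X.shape[1])], index=X.columns
    )
    return RegressionFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        vif=vif,
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        f_statistic=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        nobs=int(res.nobs),
    )


def _dependent_columns(X: pd.DataFrame) -> list[str]:
    bad = []
    for col in X.columns:
        others = X.drop(columns=[col])
        if others.shape[1] == 0:
            continue
        a = np.column_stack([np.ones(len(X)), others.to_numpy()])
        resid = X[col].to_numpy() - a @ np.linalg.lstsq(a, X[col].to_numpy(), rcond=None)[0]
        if np.allclose(resid, 0, atol=1e-10 * max(1.0, np.abs(X[col]).max())):
            bad.append(col)
    return bad or list(X.columns)


def predict_driving_time_hrv(
    lf_hf: float, rri_ms: float, msdv_z: float, coeffs: DrivingTimeCoefficients | str = "published"
) -> float:
    """Per-lap driving time (s) from the HRV model."""
    if isinstance(coeffs, str):
        coeffs = HRV_TIME_COEFFS[coeffs]
    return coeffs.predict(lf_hf, rri_ms, msdv_z)


def predict_driving_time_mse(
    mse: float, rri_ms: float, msdv_z: float, coeffs: DrivingTimeCoefficients | str = "published"
) -> float:
    """Per-lap driving time (s) from the MSE model."""
    if isinstance(coeffs, str):
        coeffs = MSE_TIME_COEFFS[coeffs]
    return coeffs.predict(mse, rri_ms, msdv_z)


@dataclass
class OperatingRecommendation:
    target_lf_hf: float
    allowable_aw: float  # m/s²
    predicted_driving_time: float  # s
    predicted_speed_ms: float  # m/s
    predicted_speed_kmh: float  # km/h
    course_length: float  # m
    inversion_mode: str


def acceptable_operation(
    rri_ms: float,
    msdv_z: float,
    target_lf_hf: float = 2.0,
    lfhf_aw_slope: float = 0.0329,
    lfhf_aw_intercept: float = 1.82,
    course_length_m: float = 400.0,
    inversion_mode: str = "as_published",
    time_coeffs: DrivingTimeCoefficients | str = "published",
) -> OperatingRecommendation:
    """Operating recommendation at an acceptable stress level.

    Inverts the stress–vibration line at ``target_lf_hf`` for the allowable
    Aw, evaluates the HRV driving-time model at the target stress with the
    given RRI and MSDVz, and converts the per-lap time to a travel speed
    over ``course_length_m``. See the module docstring for the two
    inversion modes.
    """
    if lfhf_aw_slope == 0:
        raise ValueError("slope must be non-zero")
    if inversion_mode == "as_published":
        allowable_aw = target_lf_hf / lfhf_aw_slope - lfhf_aw_intercept
    elif inversion_mode == "algebraic":
        allowable_aw = (target_lf_hf - lfhf_aw_intercept) / lfhf_aw_slope
    else:
        raise ValueError("inversion_mode must be 'as_published' or 'algebraic'")
    time_s = predict_driving_time_hrv(target_lf_hf, rri_ms, msdv_z, coeffs=time_coeffs)
    if time_s <= 0:
        raise ValueError(f"predicted driving time {time_s:.1f} s is non-positive")
    speed = course_length_m / time_s
    return OperatingRecommendation(
        target_lf_hf=target_lf_hf,
        allowable_aw=float(allowable_aw),
        predicted_driving_time=float(time_s),
        predicted_speed_ms=float(speed),
        predicted_speed_kmh=float(speed * 3.6),
        course_length=course_length_m,
        inversion_mode=inversion_mode,
    )
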