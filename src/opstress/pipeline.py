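"""End-to-end orchestration: generate → filter → metrics → stats → models → report.

``run_pipeline`` drives the whole analysis on a synthetic study: it draws a
session table with linked RR and acceleration signals, filters artifacts,
computes HRV, entropy, vibration and workload metrics per session, runs the
between-mode comparison battery, fits the driving-time regressions, and
evaluates the acceptable-stress recommendation. Everything is reproducible
from the single seed in the configuration, and every run writes a manifest
echoing the fully resolved configuration.

Two regression fits are reported: one on the generator's drawn predictors
(which estimates the generating driving-time model) and one on the metrics
actually computed from the signals (the end-to-end pipeline fit; its
predictor scales depend on the signal generators, so its coefficients are
not comparable to the generating model).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .entropy import MSEParams, rcmse
from .groupstats import compare_parameter
from .hrv import hrv_metrics
from .preprocessing import FilterParams, filter_artifacts
from .regression import acceptable_operation, fit_ols
from .synthetic import SessionRecord, generate_study_dataset, sessions_to_frame
from .vibration import vibration_metrics
from .workload import HRRInputs, compute_hrr, hr_max_age_predicted

__all__ = ["RunConfig", "run_pipeline", "analyze_session"]


@dataclass
class RunConfig:
    seed: int = 0
    n_sessions: int = 42
    signal_duration_s: float = 300.0
    artifact_filter: FilterParams = field(default_factory=FilterParams)
    mse: MSEParams = field(default_factory=MSEParams)
    alpha: float = 0.05
    coeff_preset: str = "published"
    # worked-example recommendation inputs
    target_lf_hf: float = 2.0
    lfhf_aw_slope: float = 0.0329
    lfhf_aw_intercept: float = 1.82
    recommend_rri_ms: float = 742.0
    recommend_msdv_z: float = 131.7
    course_length_m: float = 400.0
    inversion_mode: str = "as_published"
    output_dir: str | Path | None = None

    def validate(self) -> None:
        if self.n_sessions < 6:
            raise ValueError("n_sessions must be >= 6 (two per mode)")
        if self.signal_duration_s < 60:
            raise ValueError("signal_duration_s must be >= 60 s")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


#: session-table metrics compared between modes
COMPARED_PARAMETERS = (
    "mean_rri",
    "sdrr",
    "rmssd",
    "computed_lf_hf",
    "mse_ci",
    "pct_hrr",
    "aw",
    "vdv",
    "computed_msdv_z",
    "driving_time",
)


def analyze_session(
    record: SessionRecord,
    filter_params: FilterParams = FilterParams(),
    mse_params: MSEParams = MSEParams(),
) -> dict:
    """Compute every per-session metric from the record's signals."""
    if record.rri_series is None or record.accel_trace is None:
        raise ValueError("session record carries no signals; generate with with_signals=True")
    filtered = filter_artifacts(record.rri_series, filter_params)
    hrv = hrv_metrics(filtered)
    retained_rri = filtered.rri[filtered.retained_indices]
    mse_profile = rcmse(retained_rri, mse_params)
    vib = vibration_metrics(record.accel_trace)
    pct_hrr = compute_hrr(
        HRRInputs(
            hr_working=60000.0 / hrv.mean_rri,
            hr_resting=record.hr_resting,
            hr_max=hr_max_age_predicted(record.age),
        )
    )
    metrics = {
        "n_beats": len(filtered),
        "n_excluded": int(filtered.excluded.sum()),
        "mean_rri": hrv.mean_rri,
        "sdrr": hrv.sdrr,
        "rmssd": hrv.rmssd,
        "lf_power": hrv.lf_power,
        "hf_power": hrv.hf_power,
        "lf_nu": hrv.lf_nu,
        "computed_lf_hf": hrv.lf_hf,
        "valid_spectral": hrv.valid_spectral,
        "mse_ci": mse_profile.complexity,
        "aw": vib.aw,
        "vdv": vib.vdv,
        "computed_msdv_z": vib.msdv_z,
        "exposure_s": vib.T,
        "pct_hrr": pct_hrr,
    }
    record.metrics.update(metrics)
    return metrics


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns (and optionally writes) the report bundle."""
    config.validate()
    records = generate_study_dataset(
        n_sessions=config.n_sessions,
        seed=config.seed,
        with_signals=True,
        signal_duration_s=config.signal_duration_s,
    )
    for rec in records:
        analyze_session(rec, config.artifact_filter, config.mse)
    sessions = sessions_to_frame(records)

    comparisons = []
    for param in COMPARED_PARAMETERS:
        samples = {m: g[param].dropna().to_numpy() for m, g in sessions.groupby("mode")}
        if any(len(v) < 3 for v in samples.values()):
            continue
        res = compare_parameter(samples, parameter=param, alpha=config.alpha)
        row = {
            "parameter": param,
            "normality": res.normality,
            "method": res.method,
            "omnibus_p": res.omnibus_p,
        }
        for mode in res.groups:
            row[f"mean_{mode}"] = res.means[mode]
            row[f"sd_{mode}"] = res.sds[mode]
        for (a, b), p in res.pairwise_p.items():
            row[f"p_{a}_vs_{b}"] = p
        comparisons.append(row)
    comparison_table = pd.DataFrame(comparisons)

    fits = {}
    fit_truth = fit_ols(sessions["driving_time"], sessions[["lf_hf", "rri_ms", "msdv_z"]])
    fits["driving_time_on_drawn_predictors"] = fit_truth
    pipeline_X = sessions[["computed_lf_hf", "mean_rri", "computed_msdv_z"]].dropna()
    if len(pipeline_X) > 5:
        fits["driving_time_on_computed_metrics"] = fit_ols(
            sessions.loc[pipeline_X.index, "driving_time"], pipeline_X
        )

    recommendation = acceptable_operation(
        rri_ms=config.recommend_rri_ms,
        msdv_z=config.recommend_msdv_z,
        target_lf_hf=config.target_lf_hf,
        lfhf_aw_slope=config.lfhf_aw_slope,
        lfhf_aw_intercept=config.lfhf_aw_intercept,
        course_length_m=config.course_length_m,
        inversion_mode=config.inversion_mode,
        time_coeffs=config.coeff_preset,
    )

    config_echo = dataclasses.asdict(config)
    config_echo.pop("output_dir")  # execution detail, not part of the analysis
    manifest = {
        "software": {"package": "opstress", "version": __version__},
        "config": _jsonable(config_echo),
        "n_sessions": len(records),
        "total_excluded_beats": int(sessions["n_excluded"].sum()),
    }
    bundle = {
        "manifest": manifest,
        "sessions": sessions,
        "comparisons": comparison_table,
        "regressions": {
            name: _jsonable(
                {
                    "coefficients": fit.params.to_dict(),
                    "se": fit.bse.to_dict(),
                    "t": fit.tvalues.to_dict(),
                    "p": fit.pvalues.to_dict(),
                    "vif": fit.vif.to_dict(),
                    "r_squared": fit.r_squared,
                    "adj_r_squared": fit.adj_r_squared,
                    "f_statistic": fit.f_statistic,
                    "f_pvalue": fit.f_pvalue,
                    "nobs": fit.nobs,
                }
            )
            for name, fit in fits.items()
        },
        "recommendation": _jsonable(dataclasses.asdict(recommendation)),
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        sessions.to_csv(out / "sessions.csv", index=False)
        comparison_table.to_csv(out / "comparisons.csv", index=False)
        results = {
            "manifest": manifest,
            "regressions": bundle["regressions"],
            "recommendation": bundle["recommendation"],
            "comparisons": _jsonable(comparison_table.to_dict(orient="records")),
        }
        (out / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
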