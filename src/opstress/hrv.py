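"""Time- and frequency-domain heart rate variability metrics.

Time domain: mean RR interval, SDRR (sample SD of retained intervals) and
RMSSD (root mean square of successive differences, computed only between
beats that are adjacent in the original record — pairs straddling an
excluded beat are not physiologic successive differences and are skipped).

Frequency domain: the retained tachogram is cubic-spline interpolated onto
a uniform 4 Hz grid, linearly detrended, and its power spectral density
estimated by Welch's method (128 s Hann segments, 50% overlap). Band powers
are the trapezoidal integral of the PSD over LF = [0.04, 0.15) Hz and
HF = [0.15, 0.4) Hz (lower edge inclusive, upper exclusive, so the shared
0.15 Hz edge is counted once, in HF). Normalised LF power is
LF_nu = 100·LF/(LF + HF) and the sympathovagal balance index is LF/HF.

Spectral metrics refuse to run unless the artifact filter has left at least
2.5 minutes of contiguous clean data (see ``preprocessing``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal as sps

from .preprocessing import check_spectral_validity
from .signals import RRISeries

__all__ = [
    "HRVMetrics",
    "time_domain_metrics",
    "spectral_metrics",
    "hrv_metrics",
    "InsufficientDataError",
    "InvalidSpectralError",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


class InsufficientDataError(ValueError):
    """Too few retained beats for the requested metric."""


class InvalidSpectralError(ValueError):
    """Clean-segment rule not met; spectral metrics are unreliable."""


@dataclass
class HRVMetrics:
    mean_rri: float
    sdrr: float
    rmssd: float
    lf_power: float | None = None
    hf_power: float | None = None
    lf_nu: float | None = None
    lf_hf: float | None = None
    valid_spectral: bool = False


def time_domain_metrics(series: RRISeries) -> tuple[float, float, float]:
    """Return (mean_rri, sdrr, rmssd) in ms over retained beats."""
    keep = series.retained_indices
    if keep.size < 2:
        raise InsufficientDataError("need at least 2 retained beats")
    rri = series.rri[keep]
    mean_rri = float(np.mean(rri))
    sdrr = float(np.std(rri, ddof=1))
    adjacent = np.diff(keep) == 1  # successive in the original record
    diffs = np.diff(rri)[adjacent]
    if diffs.size == 0:
        raise InsufficientDataError("no adjacent retained beat pairs for RMSSD")
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    return mean_rri, sdrr, rmssd


def spectral_metrics(
    series: RRISeries,
    resample_hz: float = 4.0,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
    welch_segment_s: float = 128.0,
    min_clean_s: float = 150.0,
) -> tuple[float, float, float, float]:
    """Return (lf_power, hf_power, lf_nu, lf_hf); powers in ms²."""
    validity = check_spectral_validity(series, min_clean_s=min_clean_s)
    if not validity.valid:
        raise InvalidSpectralError(
            f"longest clean run {validity.longest_clean_s:.1f} s "
            f"< required {min_clean_s:.1f} s"
        )
    keep = series.retained_indices
    t = series.t[keep]
    rri = series.rri[keep]

    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    tach = interpolate.CubicSpline(t, rri)(grid)
    tach = sps.detrend(tach, type="linear")

    nperseg = min(int(welch_segment_s * resample_hz), tach.size)
    freqs, psd = sps.welch(
        tach, fs=resample_hz, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    lf = _band_power(freqs, psd, lf_band)
    hf = _band_power(freqs, psd, hf_band)
    if hf <= 0:
        raise InvalidSpectralError("HF power is zero; LF/HF undefined")
    return lf, hf, 100.0 * lf / (lf + hf), lf / hf


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    mask = (freqs >= band[0]) & (freqs < band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def hrv_metrics(series: RRISeries, **spectral_kwargs) -> HRVMetrics:
    """Full HRV summary; spectral fields are None when the clean-data rule fails."""
    mean_rri, sdrr, rmssd = time_domain_metrics(series)
    m = HRVMetrics(mean_rri=mean_rri, sdrr=sdrr, rmssd=rmssd)
    try:
        m.lf_power, m.hf_power, m.lf_nu, m.lf_hf = spectral_metrics(series, **spectral_kwargs)
        m.valid_spectral = True
    except InvalidSpectralError:
        m.valid_spectral = False
    return m
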