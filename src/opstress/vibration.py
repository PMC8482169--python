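"""ISO 2631-style whole-body vibration exposure indices.

Human response to vibration depends on frequency, so exposure indices are
computed on frequency-weighted acceleration. The weightings used here are
the ISO 2631-1 curves, realised as cascaded second-order analog stages
(band-limiting high/low pass, acceleration–velocity transition, upward
step) and discretised by the bilinear transform:

* ``Wk`` — vertical (z) axis, health/comfort; near-unity gain 4–8 Hz.
* ``Wd`` — horizontal (x, y) axes, health/comfort; near-unity gain 0.5–2 Hz.
* ``Wf`` — motion sickness; band-pass emphasising ≈0.1–0.5 Hz, applied to
  the vertical axis for the motion-sickness dose.
* ``flat`` — identity, for unweighted analysis.

Indices over an exposure of duration T:

* ``Aw``  — frequency-weighted RMS acceleration, per-axis RMS values
  combined vectorially: Aw = √(Σ (kᵢ·a_wᵢ)²). Time-averaged, so it can
  underestimate occasional shocks.
* ``VDV`` — vibration dose value (∫ a_w(t)⁴ dt)^{1/4}; fourth-power, hence
  peak-sensitive and cumulative in T rather than averaged.
* ``MSDVz`` — motion sickness dose value (∫ a_{Wf,z}(t)² dt)^{1/2} on the
  Wf-weighted vertical axis.

The analog low-pass band edge is clamped below the Nyquist frequency when
the sampling rate is low; for body-worn traces with content below ~12 Hz
this has no practical effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signals import AccelTrace

__all__ = [
    "VibrationMetrics",
    "apply_frequency_weighting",
    "weighting_gain",
    "compute_aw",
    "compute_vdv",
    "compute_msdv",
    "vibration_metrics",
    "WEIGHTING_PARAMS",
]

#: ISO 2631-1 weighting-stage corner frequencies (Hz) and quality factors.
#: f1/f2: band-limiting high/low pass (Q = 1/√2 each); f3, f4, Q4:
#: acceleration–velocity transition; f5, f6, Q5, Q6: upward step
#: (None = stage absent).
WEIGHTING_PARAMS: dict[str, dict] = {
    "Wk": dict(f1=0.4, f2=100.0, f3=12.5, f4=12.5, Q4=0.63, f5=2.37, f6=3.35, Q5=0.91, Q6=0.91),
    "Wd": dict(f1=0.4, f2=100.0, f3=2.0, f4=2.0, Q4=0.63, f5=None, f6=None, Q5=None, Q6=None),
    "Wf": dict(f1=0.08, f2=0.63, f3=None, f4=0.25, Q4=0.86, f5=0.0625, f6=0.1, Q5=0.8, Q6=0.8),
}

DEFAULT_AXIS_WEIGHTINGS = ("Wd", "Wd", "Wk")  # x, y horizontal; z vertical


def _analog_stages(name: str, f2_clamp: float | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Second-order (num, den) analog sections of a weighting filter."""
    try:
        p = WEIGHTING_PARAMS[name]
    except KeyError:
        raise ValueError(f"unsupported weighting {name!r}; expected Wk, Wd, Wf or flat")
    tau = 2 * np.pi
    stages = []
    w1, w2 = tau * p["f1"], tau * min(p["f2"], f2_clamp or p["f2"])
    q12 = 1 / np.sqrt(2)
    stages.append((np.array([1.0, 0.0, 0.0]), np.array([1.0, w1 / q12, w1**2])))  # HP
    stages.append((np.array([0.0, 0.0, w2**2]), np.array([1.0, w2 / q12, w2**2])))  # LP
    w4, q4 = tau * p["f4"], p["Q4"]
    if p["f3"] is None:  # transition without the proportionality zero
        num = np.array([0.0, 0.0, w4**2])
    else:
        w3 = tau * p["f3"]
        num = np.array([0.0, w4**2 / w3, w4**2])
    stages.append((num, np.array([1.0, w4 / q4, w4**2])))
    if p["f5"] is not None:  # upward step
        w5, w6 = tau * p["f5"], tau * p["f6"]
        q5, q6 = p["Q5"], p["Q6"]
        # unit gain at high frequency, (f5/f6)^2 at DC — the upward step
        stages.append((np.array([1.0, w5 / q5, w5**2]), np.array([1.0, w6 / q6, w6**2])))
    return stages


def weighting_gain(name: str, freq_hz: np.ndarray | float) -> np.ndarray | float:
    """Analytic magnitude response |H(j2πf)| of a weighting's analog prototype."""
    f = np.asarray(freq_hz, dtype=float)
    if name == "flat":
        return np.ones_like(f) if f.ndim else 1.0
    s = 1j * 2 * np.pi * f
    h = np.ones_like(s)
    for num, den in _analog_stages(name):
        h = h * np.polyval(num, s) / np.polyval(den, s)
    mag = np.abs(h)
    return mag if mag.ndim else float(mag)


def _weighting_sos(name: str, fs: float) -> np.ndarray:
    zeros, poles, gain = [], [], 1.0
    for num, den in _analog_stages(name, f2_clamp=0.45 * fs):
        z, p, k = sps.tf2zpk(np.trim_zeros(num, "f"), den)
        zeros.extend(z)
        poles.extend(p)
        gain *= k
    zd, pd, kd = sps.bilinear_zpk(np.array(zeros), np.array(poles), gain, fs)
    return sps.zpk2sos(zd, pd, kd)


def apply_frequency_weighting(trace: AccelTrace, axis: str, weighting: str) -> np.ndarray:
    """Frequency-weighted acceleration of one axis (m/s²)."""
    x = trace.axis(axis)
    if weighting == "flat":
        return x.copy()
    if weighting == "Wf" and trace.fs < 4 * 0.63:
        raise ValueError("sampling rate too low for the Wf motion-sickness band")
    return sps.sosfilt(_weighting_sos(weighting, trace.fs), x)


def _weighted_axes(trace: AccelTrace, weightings) -> list[np.ndarray]:
    if isinstance(weightings, str):
        weightings = (weightings,) * 3
    return [
        apply_frequency_weighting(trace, ax, w) for ax, w in zip(("x", "y", "z"), weightings)
    ]


def compute_aw(
    trace: AccelTrace,
    weightings=DEFAULT_AXIS_WEIGHTINGS,
    axis_multipliers: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """Frequency-weighted RMS acceleration, axes combined vectorially.

    Axis multipliers default to 1; the ISO health-assessment convention
    (k = 1.4, 1.4, 1.0) can be passed explicitly.
    """
    rms = [np.sqrt(np.mean(a**2)) for a in _weighted_axes(trace, weightings)]
    return float(np.sqrt(sum((k * r) ** 2 for k, r in zip(axis_multipliers, rms))))


def compute_vdv(trace: AccelTrace, weightings=DEFAULT_AXIS_WEIGHTINGS, axis: str | None = None) -> float:
    """Vibration dose value (m/s^1.75), fourth-power time integral.

    Uses the sample-wise vector magnitude of the weighted axes by default,
    or a single selected axis.
    """
    ws = _weighted_axes(trace, weightings)
    if axis is None:
        mag2 = ws[0] ** 2 + ws[1] ** 2 + ws[2] ** 2
    else:
        mag2 = ws["xyz".index(axis)] ** 2
    return float((np.sum(mag2**2) / trace.fs) ** 0.25)


def compute_msdv(trace: AccelTrace, weighting: str = "Wf") -> float:
    """Motion sickness dose value (m/s^1.5) on the weighted vertical axis."""
    a = apply_frequency_weighting(trace, "z", weighting)
    return float(np.sqrt(np.sum(a**2) / trace.fs))


@dataclass
class VibrationMetrics:
    aw: float
    vdv: float
    msdv_z: float
    T: float


def vibration_metrics(trace: AccelTrace, **aw_kwargs) -> VibrationMetrics:
    return VibrationMetrics(
        aw=compute_aw(trace, **aw_kwargs),
        vdv=compute_vdv(trace),
        msdv_z=compute_msdv(trace),
        T=trace.duration,
    )
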