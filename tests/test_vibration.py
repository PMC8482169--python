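"""ISO 2631 weighting filters and exposure indices."""

import numpy as np
import pytest
from scipy import signal as sps

from opstress import (
    AccelTrace,
    apply_frequency_weighting,
    compute_aw,
    compute_msdv,
    compute_vdv,
    generate_accel_trace,
    weighting_gain,
)
from opstress.vibration import _weighting_sos


def sine_trace(amp, freq, fs=100.0, T=300.0, axis="z"):
    t = np.arange(int(T * fs)) / fs
    wave = amp * np.sin(2 * np.pi * freq * t)
    zero = np.zeros_like(wave)
    axes = {"x": zero, "y": zero, "z": zero}
    axes[axis] = wave
    return AccelTrace(fs=fs, ax=axes["x"], ay=axes["y"], az=axes["z"])


# ISO 2631-1 one-third-octave tabulated gains (frequency Hz -> magnitude)
ISO_TABLE = {
    "Wk": {0.5: 0.418, 1.0: 0.482, 2.0: 0.531, 4.0: 0.967, 8.0: 1.036, 16.0: 0.768},
    "Wd": {0.5: 0.853, 1.0: 1.011, 2.0: 0.890, 4.0: 0.512, 8.0: 0.253},
    "Wf": {0.1: 0.695, 0.125: 0.895, 0.16: 1.006, 0.25: 0.854, 0.5: 0.223},
}


class TestWeightings:
    @pytest.mark.parametrize("name", ["Wk", "Wd", "Wf"])
    def test_analog_gain_matches_iso_tables(self, name):
        for f, gain in ISO_TABLE[name].items():
            assert weighting_gain(name, f) == pytest.approx(gain, rel=0.02), (name, f)

    @pytest.mark.parametrize("name,fs", [("Wk", 200.0), ("Wd", 200.0), ("Wf", 100.0)])
    def test_digital_filter_tracks_analog_response_in_band(self, name, fs):
        sos = _weighting_sos(name, fs)
        freqs = np.array(sorted(ISO_TABLE[name]))
        _, h = sps.freqz_sos(sos, worN=freqs, fs=fs)
        np.testing.assert_allclose(np.abs(h), weighting_gain(name, freqs), rtol=0.03)

    def test_flat_weighting_is_identity(self):
        tr = generate_accel_trace(30, fs=50, seed=0)
        out = apply_frequency_weighting(tr, "z", "flat")
        np.testing.assert_array_equal(out, tr.az)

    @pytest.mark.parametrize(
        "name,f_unity", [("Wk", 4.313), ("Wd", 0.8537), ("Wf", 0.1557)]
    )
    def test_sine_at_unity_gain_frequency_passes_unattenuated(self, name, f_unity):
        # f_unity found by solving |H(j2πf)| = 1 on the analog prototype
        assert weighting_gain(name, f_unity) == pytest.approx(1.0, abs=0.01)
        tr = sine_trace(1.0, f_unity, fs=100, T=600)
        out = apply_frequency_weighting(tr, "z", name)
        # skip the filter warm-up before measuring RMS
        n0 = int(100 * 100)
        rms = np.sqrt(np.mean(out[n0:] ** 2))
        assert rms == pytest.approx(1 / np.sqrt(2), rel=0.03)

    @pytest.mark.parametrize(
        "name,f_far,fs", [("Wk", 125.0, 500.0), ("Wd", 30.0, 200.0), ("Wf", 5.0, 100.0)]
    )
    def test_sine_far_above_pass_band_is_attenuated(self, name, f_far, fs):
        assert weighting_gain(name, f_far) < 0.1  # analytic magnitude check
        tr = sine_trace(1.0, f_far, fs=fs, T=120)
        out = apply_frequency_weighting(tr, "z", name)
        assert np.sqrt(np.mean(out[out.size // 2 :] ** 2)) < 0.1 / np.sqrt(2)

    def test_unknown_weighting_rejected(self):
        tr = sine_trace(1.0, 1.0, T=10)
        with pytest.raises(ValueError, match="weighting"):
            apply_frequency_weighting(tr, "z", "Wb")


class TestAw:
    def test_zero_trace_gives_zero(self):
        tr = AccelTrace(fs=50, ax=np.zeros(100), ay=np.zeros(100), az=np.zeros(100))
        assert compute_aw(tr) == 0.0
        assert compute_vdv(tr) == 0.0
        assert compute_msdv(tr) == 0.0

    def test_single_axis_sine_flat_weighting(self):
        tr = sine_trace(2.0, 1.0, T=300)
        assert compute_aw(tr, weightings="flat") == pytest.approx(2.0 / np.sqrt(2), rel=1e-6)

    def test_equal_noise_axes_combine_as_sqrt3(self):
        tr = generate_accel_trace(300, fs=50, rms_per_axis=(1, 1, 1), seed=3)
        assert compute_aw(tr, weightings="flat") == pytest.approx(np.sqrt(3), rel=0.02)

    def test_axis_multipliers_scale_contributions(self):
        tr = sine_trace(1.0, 1.0, T=60, axis="x")
        base = compute_aw(tr, weightings="flat")
        health = compute_aw(tr, weightings="flat", axis_multipliers=(1.4, 1.4, 1.0))
        assert health == pytest.approx(1.4 * base, rel=1e-9)

    def test_aw_is_time_invariant_for_stationary_signal(self):
        long = generate_accel_trace(600, fs=50, rms_per_axis=(0.5, 0.5, 0.5), seed=7)
        short = AccelTrace(fs=50, ax=long.ax[:15000], ay=long.ay[:15000], az=long.az[:15000])
        assert compute_aw(short) == pytest.approx(compute_aw(long), rel=0.1)


class TestVDV:
    def test_constant_magnitude_closed_form(self):
        n = 3000
        tr = AccelTrace(fs=10, ax=np.zeros(n), ay=np.zeros(n), az=np.full(n, 2.0))
        # |a| = c over T gives VDV = c·T^(1/4)
        assert compute_vdv(tr, weightings="flat") == pytest.approx(2.0 * 300**0.25, rel=1e-9)

    def test_sine_closed_form(self):
        tr = sine_trace(1.5, 1.0, T=300)
        expected = 1.5 * (3 * 300 / 8) ** 0.25  # mean of sin⁴ is 3/8
        assert compute_vdv(tr, weightings="flat", axis="z") == pytest.approx(expected, rel=0.01)

    def test_vdv_exceeds_rms_based_bound_for_peaked_signals(self):
        smooth = generate_accel_trace(300, fs=50, rms_per_axis=(0, 0, 0.5), seed=1)
        shocked = generate_accel_trace(
            300, fs=50, rms_per_axis=(0, 0, 0.5), shock_rate=0.05, shock_amp=4.0, seed=1
        )
        for tr in (smooth, shocked):
            rms = np.sqrt(np.mean(tr.az**2))
            assert compute_vdv(tr, weightings="flat", axis="z") > rms * 300**0.25
        assert compute_vdv(shocked, weightings="flat", axis="z") > compute_vdv(
            smooth, weightings="flat", axis="z"
        )

    def test_vdv_grows_with_duration(self):
        long = generate_accel_trace(600, fs=50, rms_per_axis=(0.5, 0.5, 0.5), seed=9)
        half = AccelTrace(fs=50, ax=long.ax[:15000], ay=long.ay[:15000], az=long.az[:15000])
        assert compute_vdv(long) > compute_vdv(half)


class TestMSDV:
    def test_msdv_equals_weighted_rms_times_sqrt_t(self):
        tr = generate_accel_trace(300, fs=50, rms_per_axis=(0.3, 0.3, 0.8), seed=5)
        weighted = apply_frequency_weighting(tr, "z", "Wf")
        rms = np.sqrt(np.mean(weighted**2))
        assert compute_msdv(tr) == pytest.approx(rms * np.sqrt(300), rel=1e-9)

    def test_doubling_duration_scales_by_sqrt2(self):
        long = generate_accel_trace(1200, fs=20, rms_per_axis=(0, 0, 0.5), band_hz=(0.1, 5), seed=2)
        half = AccelTrace(fs=20, ax=long.ax[:12000], ay=long.ay[:12000], az=long.az[:12000])
        ratio = compute_msdv(long) / compute_msdv(half)
        assert ratio == pytest.approx(np.sqrt(2), rel=0.15)

    def test_horizontal_vibration_does_not_contribute(self):
        tr = sine_trace(2.0, 0.2, fs=50, T=120, axis="x")
        assert compute_msdv(tr) == 0.0
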