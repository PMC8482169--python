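"""Time- and frequency-domain HRV of sympathetic- vs vagal-dominant rhythms.

Two synthetic 5-minute RR series differ only in which spectral band carries
the heart-rate modulation: 0.10 Hz (LF, sympathovagal) versus 0.25 Hz
(HF, respiratory/vagal). The LF/HF ratio separates them by two orders of
magnitude — the package's stress index in action.
"""

from opstress import generate_rri_series, hrv_metrics

for label, lf_amp, hf_amp in [("LF-dominant (stressed)", 0.08, 0.01), ("HF-dominant (calm)", 0.01, 0.08)]:
    series = generate_rri_series(300, mean_rri_ms=800, lf_amp=lf_amp, hf_amp=hf_amp, seed=3)
    m = hrv_metrics(series)
    print(f"{label}:")
    print(f"  mean RRI {m.mean_rri:7.1f} ms   SDRR {m.sdrr:5.1f} ms   RMSSD {m.rmssd:5.1f} ms")
    print(
        f"  LF {m.lf_power:8.1f} ms²  HF {m.hf_power:8.1f} ms²  "
        f"LF_nu {m.lf_nu:5.1f}  LF/HF {m.lf_hf:6.2f}"
    )
print("LF/HF > ~2 is read as an elevated sympathetic (stress) balance.")
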