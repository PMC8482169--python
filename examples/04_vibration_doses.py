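"""ISO 2631 vibration exposure indices and their shock sensitivity.

Aw (weighted RMS acceleration) is time-averaged; VDV integrates the fourth
power and therefore responds to occasional shocks that barely move Aw;
MSDVz accumulates Wf-weighted vertical motion in the 0.1-0.5 Hz band that
drives motion sickness.
"""

from opstress import generate_accel_trace, vibration_metrics

smooth = generate_accel_trace(300, fs=50, rms_per_axis=(0.3, 0.3, 0.5), seed=2)
shocked = generate_accel_trace(
    300, fs=50, rms_per_axis=(0.3, 0.3, 0.5), shock_rate=0.05, shock_amp=5.0, seed=2
)

for label, trace in [("smooth ride ", smooth), ("with shocks ", shocked)]:
    m = vibration_metrics(trace)
    print(
        f"{label}: Aw {m.aw:6.3f} m/s²   VDV {m.vdv:6.2f} m/s^1.75   "
        f"MSDVz {m.msdv_z:6.3f} m/s^1.5   over T = {m.T:.0f} s"
    )
print("shocks raise VDV much more than Aw: the fourth power emphasises peaks.")
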