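"""Generate a contaminated RR-interval series and remove the artifacts.

The generator emits beats from an integral pulse frequency modulation model
and corrupts a fraction of intervals by halving/doubling them (false and
missed beat detections). The moving-window filter (l=41 beats, tolerance
a=0.2) flags intervals outside ±20% of their local window mean; the
clean-segment rule then decides whether spectral HRV analysis is allowed.
"""

from opstress import FilterParams, check_spectral_validity, filter_artifacts, generate_rri_series

series = generate_rri_series(
    duration_s=300, mean_rri_ms=800, lf_amp=0.05, hf_amp=0.03, artifact_rate=0.02, seed=7
)
print(f"generated {len(series)} beats over {series.duration:.0f} s")

filtered = filter_artifacts(series, FilterParams(l=41, a=0.2))
n_flagged = int(filtered.excluded.sum())
print(f"artifact filter flagged {n_flagged} beats ({100 * n_flagged / len(series):.1f}%)")

validity = check_spectral_validity(filtered)
print(
    f"longest contiguous clean run: {validity.longest_clean_s:.1f} s -> "
    f"spectral analysis {'allowed' if validity.valid else 'refused'} "
    "(rule: at least 150 s of clean data to estimate LF power)"
)
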