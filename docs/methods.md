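# Methods

This note documents the models implemented in `opstress`, the parameter
defaults and why they were chosen, the numerical conventions, what the
synthetic generators do and do not emulate, and the known limitations.

## Signals and containers

An `RRISeries` holds beat times `t` (s) and interbeat intervals `rri`
(ms) with the invariant `t[i] − t[i−1] = rri[i]/1000`, plus per-beat
exclusion flags; an `AccelTrace` holds three equal-length axes (m/s²) at
a fixed sampling rate `fs`. Both round-trip through plain CSV
(`t_s, rri_ms[, excluded]` and `t_s, ax, ay, az`), the dialect of a
chest-sensor export. Filtering is non-destructive: downstream modules see
original values plus flags, and operate on retained beats only.

## Artifact filtering

Missed and falsely detected beats produce intervals far from their local
neighbourhood and inflate spectral power in every band. The filter slides
a centred window of `l = 41` beats; the centre beat is excluded when its
interval falls outside `m̄·(1 ± a)` with `a = 0.2`, where `m̄` is the mean
of the other beats in the window. Conventions:

* the band formula is the relative-tolerance reading `m̄·(1±a)`; with
  `a = 1` the band spans `[0, 2m̄]`, the natural maximal band;
* windows are truncated (asymmetric) at the record edges so a 5-minute
  record keeps full coverage rather than losing `(l−1)/2` beats per end;
* exclusions are computed in one pass against the original series;
  `iterative=True` repeats the pass on the retained subset until stable,
  which unmasks clusters of artifacts that inflate one-pass window means.

Spectral HRV is gated by a clean-segment rule: the longest *contiguous*
run of retained beats must span at least 150 s (2.5 min), measured as the
summed duration of its intervals, threshold inclusive. The contiguity
reading is deliberate — scattered exclusions leave no uninterrupted
segment for low-frequency power estimation even when the total retained
time is large.

## HRV

Time domain: mean RRI, SDRR (sample SD, ddof = 1), RMSSD over successive
differences of beats *adjacent in the original record*; pairs straddling
an excluded beat are skipped because a bridged difference is not a
physiologic successive difference.

Frequency domain: the retained tachogram is cubic-spline interpolated to
4 Hz, linearly detrended, and estimated with Welch (Hann window, 128 s
segments, 50% overlap) — the de facto standard for 5-minute records; all
parameters are arguments. Band powers are trapezoidal integrals over
LF = [0.04, 0.15) Hz and HF = [0.15, 0.4) Hz; half-open bands assign the
shared 0.15 Hz edge to HF exactly once. `LF_nu = 100·LF/(LF+HF)`, so
`LF_nu + HF_nu = 100` by construction. A Parseval property (in-band power
within 15% of the detrended tachogram variance for band-limited synthetic
inputs) is enforced in the test suite.

## Multiscale entropy

`SampEn(m, r)` is `−ln(A/B)` with Chebyshev distance, self-matches
excluded, and the *same* template range (the first `n − m` positions)
used at both lengths, so `A ≤ B` always and a constant series gives
`A = B` → entropy exactly 0. Published implementations differ on this
edge case; the matched-range convention is documented here because the
robustness of the refined composite variant depends on it.

RCMSE at scale τ forms all τ coarse-grained series (offsets 0…τ−1,
non-overlapping window means), sums the match counts over offsets, and
takes `−ln(ΣA/ΣB)`. The radius is fixed once at `r = 0.15·SD` of the
original series and reused at all scales (per-scale `r` available behind
a flag); `m = 2`, scales 1–14, matching the study parameters for
≈5-minute RR records (≈400 beats, comfortably inside the ≤750-point
regime where composite variants remain reliable). A scale is flagged
undefined when no matches exist at either length across all offsets; the
complexity index — the trapezoidal area under the entropy–scale curve,
units nats·scale — is only reported when every scale is defined.

The entropy input is the artifact-filtered RRI sequence on the beat index
(not interpolated time), since single outlier intervals dominate the
similarity counts otherwise.

## Vibration indices

The ISO 2631-1 weightings are cascades of second-order analog stages:
band-limiting two-pole high pass (`f1`) and low pass (`f2`, Q = 1/√2),
an acceleration–velocity transition (`f3`, `f4`, `Q4`), and for Wk/Wf an
upward-step stage (`f5`, `f6`, `Q5`, `Q6`) with unit gain at high
frequency and `(f5/f6)²` at DC. The stage corner parameters are the
standard's; the resulting analog magnitudes reproduce the tabulated
one-third-octave gains to within ~1% at every checked frequency (Wk at
0.5–16 Hz, Wd at 0.5–8 Hz, Wf at 0.1–0.5 Hz), and the test suite pins
those values at 2%. Digitisation is bilinear (`zpk` → second-order
sections); the analog low-pass edge is clamped to `0.45·fs` when the
sampling rate cannot represent it, which is irrelevant below ~12 Hz where
body-worn content lives. Filters are causal; for unity-gain checks the
tests discard the warm-up transient.

Index definitions over exposure time `T`:

* `Aw`: per-axis weighted RMS (Wd, Wd, Wk by default) combined
  vectorially with axis multipliers `k = (1, 1, 1)` by default (ISO
  health-assessment `1.4, 1.4, 1.0` selectable). The per-axis-RMS-first
  order of operations is the ISO convention.
* `VDV = (∫ a_w⁴ dt)^{1/4}` on the sample-wise weighted vector magnitude
  (or one axis); peak-sensitive and cumulative, `c·T^{1/4}` for constant
  magnitude `c`, `A·(3T/8)^{1/4}` for a sine of amplitude `A`.
* `MSDVz = (∫ a_{Wf,z}² dt)^{1/2}`, i.e. weighted RMS·√T for stationary
  signals.

Reported group-level magnitudes in the source study (Aw ≈ 60 m/s², VDV in
the thousands) are far above SI whole-body exposure values and imply an
unstated device scale factor; this package computes strictly in SI m/s²
and makes no attempt to reproduce those magnitudes. The fixed regression
equations take the study-scale MSDVz as a plain numeric input, so the
worked example is unaffected.

## Workload

`%HRR = (HR_work − HR_rest)/(HR_max − HR_rest)·100` with
`HR_work = 60000 / mean retained RRI` and `HR_max = 220 − age` by default
(the source study says only "based on age"; Tanaka `208 − 0.7·age` is
provided as an alternative). Negative values are reported, not clipped.

## Group statistics

Normality triage: a parameter is "P" only when every group passes both
Shapiro-Wilk and the Lilliefors-corrected KS test at α = .05. Lilliefors
is used because the group mean/SD are estimated from the same data, and
the plain KS test is anti-conservative then; below n = 4 (no Lilliefors
table) Shapiro-Wilk decides alone. Constant groups are "NP" with a
warning.

"P" → one-way ANOVA omnibus + pairwise t tests with Bonferroni
adjustment (×3, capped at 1). "NP" → tie-corrected Kruskal-Wallis +
Steel-Dwass: per pair, the pooled-rank Mann-Whitney statistic is
standardised with the tie-corrected variance and `|t|·√2` referred to the
studentized range distribution with k groups (df = ∞), the standard
large-sample form. An exact permutation mode enumerates all pooled splits
for small groups; for k = 2 the asymptotic reference collapses to the
two-sided normal p, which the tests exploit as an oracle equivalence.
Null calibration (any-pair rejection ≤ α up to Monte-Carlo error at
n = 14/group) is enforced in the acceptance suite.

## Regression and the recommendation

`fit_ols` wraps statsmodels OLS with an intercept: SEs, two-sided p from
the t distribution with `n − p − 1` df (sidedness is a package choice),
VIF from auxiliary regressions, R²/adjusted R², overall F. Rank-deficient
designs raise an error naming the dependent columns.

The driving-time equations ship as two named presets each: the rounded
coefficients printed with the published worked example
(`−24.5, −0.35, −10.7, 2115` and `10.5, −0.259, −10.3, 1823`) and the
full-precision table estimates (intercepts 2115.6 / 1823.3). The
`published` preset is the default because the printed 397.1 s arises from
the rounded set.

The acceptable-stress recommendation inverts `LF/HF = 0.0329·Aw + 1.82`
at a target `LF/HF = 2`. The published inversion evaluates
`Aw = 2/0.0329 − 1.82 ≈ 59`, which is **not** the algebraic inverse of
that line (that would be `(2 − 1.817)/0.0329 ≈ 5.6`). Both modes are
implemented; `as_published` is the default so the worked example
reproduces, and the discrepancy is surfaced in the API docstring rather
than silently "fixed". The recommendation then evaluates the HRV
driving-time model at the target stress with the supplied reference
RRI/MSDVz and converts to speed over the course length, so
`speed × time = course length` holds exactly.

## Synthetic data: what it emulates, and what it does not

* **RR series** come from an IPFM model: rate
  `r(t) = (1 + a_LF·sin(2π·0.10t) + a_HF·sin(2π·0.25t))/T0`, beats at
  integer crossings of its exact closed-form integral. This gives
  analytic control of band placement (LF:HF power ≈ `(a_LF/a_HF)²`) and a
  mean interval within 1% of `T0` over ≥ 300 s. Artifacts halve or double
  randomly chosen intervals (false/missed detections) and beat times are
  rebuilt, preserving the container invariant. Real RR series have
  broadband (not two-tone) modulation, respiratory frequency drift and
  nonstationarity; passing tests therefore validate the *estimators'*
  frequency selectivity and the filter's outlier logic, not physiologic
  realism.
* **Acceleration** is per-axis band-limited Gaussian noise (0.2–12 Hz by
  default, covering the whole-body-relevant range) rescaled to an exact
  target RMS, plus optional Poisson-timed 120 ms half-sine vertical
  shocks. Real machine vibration has resonant spectral structure; the
  generator only guarantees controlled RMS and controlled peakedness.
* **Session tables** assign modes round-robin and draw (LF/HF, RRI,
  MSDVz) per mode from Gaussian profiles centred on the published group
  means/SDs (riding 4.72/664.8/133.9, remote 1.85/828.9/126.5, VR
  3.27/803.0/131.3), truncated to physiologic bounds (RRI 400–1500 ms,
  LF/HF > 0.05, MSDVz > 0). Driving time is the fixed HRV model at the
  drawn predictors plus Gaussian noise. The default residual SD is not a
  free dial: `calibrate_noise_sd` solves the closed-form mixture-variance
  relation so the population adjusted R² of a refit equals the published
  0.449 at n = 42 (truncation ignored; a < 1% effect at these profiles).
  With-signals generation additionally attaches an IPFM series whose mean
  interval and amplitude ratio target the drawn RRI and LF/HF, and an
  acceleration trace whose vertical RMS increases with the drawn MSDVz —
  the computed signal metrics approximate, but do not equal, the drawn
  predictors, which is why the pipeline reports the drawn-predictor refit
  and the computed-metric fit separately. The per-session artifact rate
  is kept low (0.002/beat) because the contiguous clean-segment rule
  would otherwise disqualify most sessions from spectral analysis.
* **Seeding**: one user seed fans out through numpy `SeedSequence.spawn`
  into independent child streams per component, so identical seeds give
  bit-identical outputs everywhere.

## Problem sizes

Defaults used by the tests and the reproduction script: 5-minute records
(≈375 beats at 800 ms; 300 s of acceleration at 50–100 Hz), 42-session
studies, 100-pair noise-discrimination runs at n = 750, 500-replicate
parameter-recovery runs, and 400-replicate null-calibration runs at
n = 14/group. These match the scales the analysis is designed for while
keeping a full test run in a few minutes on one core.

## Known limitations

* The 42 published measurements pool repeated sessions from 9 operators;
  the models here reproduce that pooled OLS and make no within-subject
  correlation adjustment (no mixed-effects variant), by design.
* Table-level group means of the source study are used only as generator
  plausibility centres; its p values and absolute vibration magnitudes
  are not reproducible without the undeposited recordings and are covered
  by calibration property tests instead.
* Absolute LF/HF from 5-minute Welch estimates carries well-known
  estimator variance; tests use ±20% tolerances on power ratios, and
  single-session values should be read accordingly.
* The Wf implementation targets the motion-sickness band (~0.02–0.6 Hz);
  at sampling rates below ~20 Hz or analysis bands pushed toward Nyquist
  the bilinear mapping deviates from the analog curve (the tests quantify
  the agreement region).
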