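"""Artifact and error-beat removal for RR-interval series.

Missed or spuriously detected heartbeats produce intervals far from their
local neighbourhood; left in place they inflate power in every HRV frequency
band and can dominate entropy estimates. The filter used here flags any beat
whose interval falls outside a relative-tolerance band around the mean of
the other beats in a centred moving window:

    excluded  ⇔  rri outside [ m̄·(1 − a), m̄·(1 + a) ]

where m̄ is the window mean computed *excluding the centre point*. The
study-standard parameters are window length l = 41 beats and tolerance
a = 0.2. Windows are truncated (asymmetric) at the edges so short records
keep full coverage. Filtering is non-destructive: values are retained with
an exclusion flag.

Spectral HRV analysis additionally needs a sufficiently long artifact-free
stretch; ``check_spectral_validity`` implements the rule that at least 2.5
minutes of clean data are required to estimate LF power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import RRISeries

__all__ = ["FilterParams", "filter_artifacts", "check_spectral_validity", "SpectralValidity"]


@dataclass(frozen=True)
class FilterParams:
    """Moving-window artifact-filter parameters.

    l : window length in beats (odd, ≥ 3); a : relative tolerance in (0, 1].
    With a = 1 the band spans [0, 2·m̄], the widest allowed.
    """

    l: int = 41
    a: float = 0.2

    def __post_init__(self) -> None:
        if self.l < 3 or self.l % 2 == 0:
            raise ValueError("window length l must be odd and >= 3")
        if not 0 < self.a <= 1:
            raise ValueError("tolerance a must lie in (0, 1]")


def filter_artifacts(
    series: RRISeries, params: FilterParams = FilterParams(), iterative: bool = False
) -> RRISeries:
    """Flag artifact beats; returns a copy with ``excluded`` set.

    All window means are computed against the original series in a single
    pass (the default). With ``iterative=True`` the pass is repeated on the
    retained subset until no further beat is flagged, which removes clusters
    of artifacts that mask each other.
    """
    n = len(series)
    if n < 3:
        raise ValueError("series too short to filter (need at least 3 beats)")

    excluded = _one_pass(series.rri, params)
    if iterative:
        while True:
            keep = np.flatnonzero(~excluded)
            if keep.size < 3:
                break
            new = _one_pass(series.rri[keep], params)
            if not new.any():
                break
            excluded[keep[new]] = True
    return series.with_flags(excluded)


def _one_pass(rri: np.ndarray, params: FilterParams) -> np.ndarray:
    n = rri.size
    half = params.l // 2
    csum = np.concatenate([[0.0], np.cumsum(rri)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    window_sum = csum[hi + 1] - csum[lo]
    count = hi - lo  # window size minus the centre point
    mean_others = (window_sum - rri) / count
    return (rri < mean_others * (1 - params.a)) | (rri > mean_others * (1 + params.a))


@dataclass(frozen=True)
class SpectralValidity:
    valid: bool
    longest_clean_s: float


def check_spectral_validity(series: RRISeries, min_clean_s: float = 150.0) -> SpectralValidity:
    """Whether the longest contiguous non-excluded stretch covers ``min_clean_s``.

    The stretch length is the summed duration of its consecutive retained
    intervals (seconds); the threshold is inclusive. An empty or fully
    excluded series is invalid with run length 0.
    """
    keep = ~series.excluded
    if not keep.any():
        return SpectralValidity(False, 0.0)
    best = 0.0
    run = 0.0
    for k, dur in zip(keep, series.rri / 1000.0):
        run = run + dur if k else 0.0
        best = max(best, run)
    return SpectralValidity(best >= min_clean_s, float(best))
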