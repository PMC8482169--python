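"""Workload intensity as percentage heart rate reserve (%HRR).

    %HRR = (HR_working − HR_resting) / (HR_max − HR_resting) × 100

HR_working is the mean working heart rate over the session; HR_max defaults
to the age-predicted 220 − age (the Tanaka estimate 208 − 0.7·age is also
available). Values may be negative when the working rate dips below rest;
they are reported as-is, not clipped. As a guide, sustained work at
30–40 %HRR is the range where occupational-physiology guidance urges
caution for construction workers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hrv import time_domain_metrics
from .signals import RRISeries

__all__ = ["HRRInputs", "compute_hrr", "hr_max_age_predicted", "hr_max_tanaka", "hrr_from_series"]


def hr_max_age_predicted(age_years: float) -> float:
    """Classic age-predicted maximum heart rate, 220 − age (bpm)."""
    return 220.0 - age_years


def hr_max_tanaka(age_years: float) -> float:
    """Tanaka maximum heart rate estimate, 208 − 0.7·age (bpm)."""
    return 208.0 - 0.7 * age_years


@dataclass(frozen=True)
class HRRInputs:
    hr_working: float
    hr_resting: float
    hr_max: float

    def __post_init__(self) -> None:
        if self.hr_resting <= 0:
            raise ValueError("resting heart rate must be positive")
        if self.hr_max <= self.hr_resting:
            raise ValueError("hr_max must exceed hr_resting (degenerate denominator)")


def compute_hrr(inputs: HRRInputs) -> float:
    """Percentage heart rate reserve."""
    return (
        (inputs.hr_working - inputs.hr_resting)
        / (inputs.hr_max - inputs.hr_resting)
        * 100.0
    )


def hrr_from_series(
    series: RRISeries, hr_resting: float, age_years: float, formula=hr_max_age_predicted
) -> float:
    """%HRR with the working rate taken as 60000 / mean retained RRI."""
    mean_rri, _, _ = time_domain_metrics(series)
    return compute_hrr(
        HRRInputs(hr_working=60000.0 / mean_rri, hr_resting=hr_resting, hr_max=formula(age_years))
    )
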