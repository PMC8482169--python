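import numpy as np
import pytest

from opstress import generate_rri_series


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def clean_lf_series():
    """5-minute IPFM series with a pure 0.10 Hz (LF) modulation."""
    return generate_rri_series(300, mean_rri_ms=800, lf_amp=0.08, hf_amp=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_hf_series():
    """5-minute IPFM series with a pure 0.25 Hz (HF) modulation."""
    return generate_rri_series(300, mean_rri_ms=800, lf_amp=0.0, hf_amp=0.08, seed=12)
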