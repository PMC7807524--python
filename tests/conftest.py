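import numpy as np
import pytest

from livertrack import (BreathingParams, CorrelationParams, MotionTrace,
                        simulate_session)


@pytest.fixture(scope="session")
def short_session():
    """60 s paired session with the default noise/drift structure."""
    return simulate_session(BreathingParams(duration_s=60.0),
                            CorrelationParams(), seed=7)


@pytest.fixture(scope="session")
def affine_session():
    """Noise-free session whose internal trace is exactly 0.8*ext + 1 mm."""
    params = BreathingParams(duration_s=120.0, noise_sd_mm=0.0)
    corr = CorrelationParams(gain=(0.8, 0.8, 0.8), gain_drift_per_min=0.0,
                             lag_s=0.0, offset_mm=1.0,
                             internal_noise_sd_mm=0.0)
    return simulate_session(params, corr, seed=3)


@pytest.fixture
def ramp_trace():
    """Deterministic linear ramps on all three axes, 20 Hz."""
    n = 200
    values = np.column_stack([np.linspace(0, 5, n), np.linspace(-2, 2, n),
                              np.linspace(1, 4, n)])
    return MotionTrace(values, sampling_rate_hz=20.0)
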