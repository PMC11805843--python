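import numpy as np
import pytest

from sbvi.waveforms import EchoInputs


@pytest.fixture
def cohort_echo() -> EchoInputs:
    """Echo scalars at typical severe-AS cohort means."""
    return EchoInputs(
        heart_rate=75.0,
        peak_velocity=425.0,
        acceleration_time=0.119,
        stroke_volume=74.0,
        aortic_valve_area=0.71,
        systolic_bp=138.0,
        diastolic_bp=75.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)
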