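import numpy as np
import pytest

from spindletwist import (
    Calibration,
    SyntheticSpindleParams,
    generate_traces,
    render_stack,
)


@pytest.fixture(scope="session")
def calib() -> Calibration:
    return Calibration()


@pytest.fixture(scope="session")
def left_handed_spindle():
    """One noisy left-handed synthetic spindle shared across tests."""
    params = SyntheticSpindleParams(twist_deg_per_um=-2.0, seed=3)
    traces, poles, truth = generate_traces(params)
    stack = render_stack(traces, params)
    return params, traces, poles, truth, stack


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
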