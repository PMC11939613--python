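import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cawave import synth

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def daoy_params() -> synth.TraceGenParams:
    """Cell-line-like recording conditions: 60 s at 15 fps, baseline 100 a.u.,
    noise SD 3, 2.5-fold transients of 40 s nominal width."""
    return synth.TraceGenParams()


@pytest.fixture
def primary_params() -> synth.TraceGenParams:
    """Primary-culture-like conditions: two-fold transients, ~50 s wide."""
    return synth.TraceGenParams(peak_fold=2.0, peak_width_s=50.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
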