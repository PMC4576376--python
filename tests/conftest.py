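import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_csv(tmp_path):
    """3-row, 6-channel log at 40 Hz (25 ms sample interval)."""
    p = tmp_path / "small.csv"
    p.write_text(
        "day,h,min,s,ms,ax,ay,az\n"
        "0,0,0,0,0,0.0,0.0,1.0\n"
        "0,0,0,0,25,0.1,0.0,0.99\n"
        "0,0,0,0,50,-0.1,0.0,1.01\n"
    )
    return p
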