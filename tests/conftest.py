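import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture()
def small_recording():
    """Tiny 3-channel recording with an 8 Hz tremor-like component."""
    from tremorsync.io_core import Condition, Recording

    fs = 128.0
    t = np.arange(int(10 * fs)) / fs
    gen = np.random.default_rng(42)
    s = np.cos(2 * np.pi * 8.0 * t)
    samples = np.vstack(
        [
            0.2 * s + 0.01 * gen.standard_normal(t.size),
            0.3 * s + 0.01 * gen.standard_normal(t.size),
            0.9 * s + 0.01 * gen.standard_normal(t.size),
        ]
    )
    return Recording(
        samples=samples,
        fs=fs,
        channel_names=["acc_x", "acc_y", "acc_z"],
        block_id="tiny",
        condition=Condition.INITIAL,
    )
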