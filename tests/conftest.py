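import numpy as np
import pytest

from gravimetrics.io_signals import SampledSignal
from gravimetrics.synthetic import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Down-scaled synthetic world for fast end-to-end runs (same injected
    effects and noise as the defaults; fewer/shorter trials, envelope-level
    EMG at 200 Hz)."""
    return SynthConfig(
        n_young=4,
        n_older=4,
        task_kinematics={
            "ARM": (0.50, 0.45, 2.5),
            "STS_BTS": (0.35, 1.40, 2.5),
            "WBR_D1": (0.60, 1.20, 2.5),
            "WBR_D2": (0.75, 1.40, 2.5),
        },
        trials_per_direction={
            "ARM": (2, 4),
            "STS_BTS": (2, 4),
            "WBR_D1": (2, 4),
            "WBR_D2": (2, 4),
        },
        emg_rate=200.0,
    )


def make_signal(values, rate=1000.0, t0=0.0):
    return SampledSignal(np.asarray(values, dtype=float), rate=rate, t0=t0)
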