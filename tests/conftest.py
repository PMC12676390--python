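import numpy as np
import pytest

from neurolatent.signals import DEFAULT_BANDS
from neurolatent.synth import BurstSpec, SignalSimConfig


def planted_burst_config(seed: int) -> SignalSimConfig:
    """High-contrast planted-burst fixture.

    10 bursts x 0.3 s at a 16 Hz low-beta carrier over a 12 s epoch put the
    burst time fraction at exactly the 75th-percentile threshold's 25%, which
    makes percentile-threshold detection unbiased (see docs/methods.md). The
    epoch is shorter than the 15 s real-data minimum, so the fixture lowers
    ``min_duration_s`` explicitly.
    """
    return SignalSimConfig(
        duration_s=12.0,
        min_duration_s=12.0,
        fs=1000.0,
        background_scale=0.05,
        bursts=(
            BurstSpec(
                "low_beta", carrier_hz=16.0, rate_hz=10.0 / 12.0,
                duration_s=0.3, amplitude=1.0, baseline=0.2,
            ),
        ),
        seed=seed,
    )


@pytest.fixture
def low_beta():
    return DEFAULT_BANDS[1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def jaccard(w: np.ndarray, w_true: np.ndarray) -> float:
    a, b = set(np.flatnonzero(w)), set(np.flatnonzero(w_true))
    return len(a & b) / len(a | b) if (a | b) else 1.0
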