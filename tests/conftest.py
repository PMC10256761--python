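"""Shared fixtures: seeded samplers for quaternions and smooth series."""

import numpy as np
import pytest

from quatsmooth import QuaternionSeries, qexp


def make_smooth_series(seed: int, n: int = 128, amplitude: float = 0.5) -> QuaternionSeries:
    """Random low-frequency curve in log coordinates, mapped to H_1.

    Three harmonics per component with geometrically decaying weights
    give a smooth, well-sampled rotation path whose adjacent relative
    rotations are far below pi — the regime both tangent transforms are
    designed for.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n)
    curve = np.zeros((n, 3))
    for k in range(1, 4):
        amp = rng.uniform(-amplitude, amplitude, 3) / k
        phase = rng.uniform(0, 2 * np.pi, 3)
        curve += amp * np.sin(2 * np.pi * k * t[:, None] + phase)
    return QuaternionSeries(qexp(curve), h=1.0 / (n - 1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def smooth_series():
    return make_smooth_series(0)


@pytest.fixture
def quaternion_alphabet():
    """Four fixed, well-separated unit quaternions for DTW enumeration."""
    return np.array(
        [
            qexp(np.array([0.0, 0.0, 0.0])),
            qexp(np.array([0.4, 0.0, 0.0])),
            qexp(np.array([0.0, 0.9, 0.0])),
            qexp(np.array([0.3, -0.2, 0.7])),
        ]
    )
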