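import numpy as np
import pytest


def disk_mask(radius: float, pad: int = 5, centre_offset=(0.0, 0.0)) -> np.ndarray:
    """Rasterized disk: pixel centres within `radius` of the disk centre."""
    size = int(2 * (radius + pad) + 1)
    c = (size - 1) / 2
    rr, cc = np.mgrid[:size, :size]
    return np.hypot(rr - c - centre_offset[0], cc - c - centre_offset[1]) <= radius


def ellipse_mask(a: float, b: float, pad: int = 5) -> np.ndarray:
    """Rasterized axis-aligned ellipse with semi-axes (a, b) = (row, col)."""
    size = int(2 * (max(a, b) + pad) + 1)
    c = (size - 1) / 2
    rr, cc = np.mgrid[:size, :size]
    return ((rr - c) / a) ** 2 + ((cc - c) / b) ** 2 <= 1


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
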