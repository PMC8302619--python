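import numpy as np
import pytest

from punctakit.core import CellMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_mask_20um():
    """20×20 µm all-true mask at 100 nm pixels (200×200)."""
    return CellMask(np.ones((200, 200), bool), 100.0)


@pytest.fixture
def small_mask():
    """12.8×12.8 µm all-true mask at 100 nm pixels (128×128)."""
    return CellMask(np.ones((128, 128), bool), 100.0)


def gaussian_frame(shape, yc, xc, amplitude=100.0, sigma=1.5, pedestal=0.0):
    """Noiseless Gaussian spot rendered by point sampling at pixel centres."""
    yy = np.arange(shape[0], dtype=float)[:, None]
    xx = np.arange(shape[1], dtype=float)[None, :]
    return pedestal + amplitude * np.exp(
        -((yy - yc) ** 2 + (xx - xc) ** 2) / (2.0 * sigma**2))
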