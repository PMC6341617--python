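import numpy as np
import pytest

from fats.core import PixelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def grid(values, pitch=1.0, dtype=np.uint8):
    """Convenience: wrap a nested list / array as a PixelGrid."""
    return PixelGrid(np.asarray(values, dtype=dtype), pitch)


def disc_image(shape, cy, cx, radius, value=200, background=0, pitch=1.0):
    """Hard-edged disc on constant background."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, background, dtype=np.float64)
    img[np.hypot(yy - cy, xx - cx) <= radius] = value
    return PixelGrid(img.astype(np.uint8), pitch)


def naive_local_gaussian_binarize(values, size, offset=0.0):
    """Independent double-loop reference for the adaptive thresholder.

    Builds the unit-sum Gaussian kernel by direct evaluation of its closed
    form, edge-replicates the image, and compares each pixel against the
    weighted mean of its own z x z window with an explicit O(z^2) sum.
    """
    sigma = 0.3 * ((size - 1) / 2 - 1) + 0.8
    half = (size - 1) // 2
    ax = np.arange(-half, half + 1, dtype=float)
    kern = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma**2))
    kern /= kern.sum()
    padded = np.pad(values.astype(np.float64), half, mode="edge")
    h, w = values.shape
    out = np.zeros((h, w), dtype=np.uint8)
    thresh = np.zeros((h, w), dtype=np.float64)
    for i in range(h):
        for j in range(w):
            window = padded[i : i + size, j : j + size]
            t = float((window * kern).sum()) - offset
            thresh[i, j] = t
            out[i, j] = 255 if values[i, j] > t else 0
    return out, thresh
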