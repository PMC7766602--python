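import numpy as np
import pytest

from capedema.imagemodel import CalibratedImage


@pytest.fixture
def rng():
    return np.random.default_rng(20201218)


@pytest.fixture
def constant_image():
    return CalibratedImage(np.full((64, 64), 0.5), pitch_um=1.0)


def as_image(arr, pitch=1.0):
    return CalibratedImage(np.asarray(arr, dtype=float), pitch_um=pitch)


def dense_gaussian(img, sigma, truncate=4.0):
    """Reference Gaussian blur: explicit truncated sampled kernel, symmetric
    (reflect-about-edge) padding, dense convolution.  Independent of scipy's
    filter pipeline; used as the oracle for the DoG implementation."""
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    K = np.outer(k, k)
    p = np.pad(img, r, mode="symmetric")
    H, W = img.shape
    out = np.empty((H, W))
    for i in range(H):
        for j in range(W):
            out[i, j] = (p[i:i + 2 * r + 1, j:j + 2 * r + 1] * K).sum()
    return out
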