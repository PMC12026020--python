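import numpy as np
import pytest

from retina_saliency import (
    LuminanceImage,
    RetinaParams,
    SceneSpec,
    generate_sample,
)


@pytest.fixture(scope="session")
def default_params() -> RetinaParams:
    return RetinaParams()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def dark_sample():
    """One default dark-corner scene with fixations and density."""
    return generate_sample(SceneSpec(seed=0))


@pytest.fixture(scope="session")
def random_image(rng) -> LuminanceImage:
    return LuminanceImage(rng.random((32, 32)), 1.0)


def dense_gaussian(arr: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Independent dense-convolution oracle for the Gaussian low-pass:
    explicit 2-D kernel, symmetric (half-sample reflective) padding, direct
    windowed summation."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    padded = np.pad(arr, radius, mode="symmetric")
    h, w = arr.shape
    out = np.empty((h, w), dtype=np.float64)
    size = 2 * radius + 1
    for i in range(h):
        for j in range(w):
            out[i, j] = (padded[i : i + size, j : j + size] * kernel).sum()
    return out


def exhaustive_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Brute-force Mann–Whitney AUC: fraction of (positive, negative) pairs
    ranked correctly, ties counted half."""
    pos = np.asarray(pos, dtype=float)[:, None]
    neg = np.asarray(neg, dtype=float)[None, :]
    wins = (pos > neg).sum() + 0.5 * (pos == neg).sum()
    return float(wins / (pos.size * neg.size))
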