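import numpy as np
import pytest

from swarmseg import entropy, pso


@pytest.fixture
def uniform_hist() -> entropy.Histogram:
    """Uniform 256-level histogram; closed-form Kapur optimum at t = 127."""
    return entropy.Histogram(np.ones(256, dtype=np.int64))


@pytest.fixture
def unit_bounds() -> pso.SearchBounds:
    return pso.SearchBounds([0.0], [255.0])


def quadratic(x: np.ndarray) -> float:
    """1-D concave benchmark with its unique maximum (value 0) at t = 128."""
    return -float((x[0] - 128.0) ** 2)


@pytest.fixture
def bimodal_image() -> tuple[np.ndarray, np.ndarray]:
    """Two-class image with non-overlapping intensity modes and its truth mask.

    Background ~ N(60, 10) and target ~ N(180, 10), each hard-clipped at
    two standard deviations so the gray levels (80, 160) carry no mass and
    the classes are exactly separable.
    """
    rng = np.random.default_rng(5)
    img = np.clip(rng.normal(60, 10, (128, 128)), 40, 80)
    truth = np.zeros((128, 128), dtype=np.uint8)
    truth[20:108, 20:108] = 1
    img[truth == 1] = np.clip(rng.normal(180, 10, int(truth.sum())), 160, 200)
    return img.astype(np.uint8), truth
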