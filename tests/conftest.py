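import numpy as np
import pytest

from ivoct_lumen import BinaryMask, GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


def disk_mask(side: int, radius: float, center=None) -> np.ndarray:
    """Analytic centred disk: pixels whose centre is within ``radius``."""
    c = (side - 1) / 2.0 if center is None else center
    cr, cc = (c, c) if np.isscalar(c) else c
    rr, cols = np.indices((side, side))
    return np.hypot(rr - cr, cols - cc) < radius


def disk_image(side: int, radius: float, value: float = 1.0) -> GrayImage:
    return GrayImage(disk_mask(side, radius).astype(float) * value)


def step_polar_mask(n_r: int, n_theta: int, row: int) -> BinaryMask:
    """Bottom-attached polar mask: rows >= ``row`` foreground everywhere."""
    m = np.zeros((n_r, n_theta), dtype=bool)
    m[row:, :] = True
    return BinaryMask(m, domain="polar")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.count_nonzero(a & b) / denom if denom else 1.0
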