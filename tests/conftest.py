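import numpy as np
import pytest

from histomulti.synthetic import SyntheticSlideSpec, generate_patch_pair


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale rendering spec: 128-px canvas -> 32x32 patch pairs."""
    return SyntheticSlideSpec(seed=7, canvas_px=128)


@pytest.fixture(scope="session")
def pair_pool(small_spec):
    """24 synthetic pairs shared by module tests."""
    return [generate_patch_pair(small_spec, i) for i in range(24)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def finite_diff(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar f at x (float64)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f(x)
        x[idx] = orig - eps
        fm = f(x)
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


def rel_err(a: np.ndarray, b: np.ndarray) -> float:
    denom = max(np.abs(a).max(), np.abs(b).max(), 1e-12)
    return float(np.abs(a - b).max() / denom)
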