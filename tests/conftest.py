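import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disk_stack():
    """Ground-truth slice stack of smooth disks with varying radius."""
    from dipchar.lsrecon import SliceStack

    K, R, C = 24, 64, 64
    yy, xx = np.mgrid[:R, :C]
    masks = np.stack(
        [
            (np.hypot(yy - 32, xx - 32) < 10 + 4 * np.sin(k / 4)).astype(np.uint8)
            for k in range(K)
        ]
    )
    return SliceStack(masks, layer_height_um=50.0)


def ols_oracle(x, y):
    """Closed-form normal-equation OLS (slope, intercept): the independent
    reference every regression in the package is checked against."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[0]), float(coef[1])
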