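import warnings

import numpy as np
import pytest

from cindy.io import SmallSampleWarning


@pytest.fixture(autouse=True)
def _quiet_small_sample():
    """Most tests use deliberately small matrices; the warning is tested once."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallSampleWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def gaussian_pair(rho: float, n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.random.default_rng(seed)
    uv = r.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    return uv[:, 0], uv[:, 1]
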