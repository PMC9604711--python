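import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20220291)


def random_masks(rng, n, shape=(64, 64), densities=(0.05, 0.5)):
    """Seeded random binary masks spanning a density sweep."""
    lo, hi = densities
    for i in range(n):
        d = lo + (hi - lo) * i / max(n - 1, 1)
        yield rng.random(shape) < d
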