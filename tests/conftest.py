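import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_standardized(rng):
    """A 20 x 10 standardized matrix with mild random correlation."""
    from carsnp import standardize_columns

    base = rng.standard_normal((20, 4))
    mix = rng.standard_normal((4, 10))
    raw = base @ mix + 0.8 * rng.standard_normal((20, 10))
    return standardize_columns(raw)


@pytest.fixture
def duplicated_pair():
    """n=30 matrix with two identical standardized columns."""
    from carsnp import standardize_columns

    rng = np.random.default_rng(7)
    col = rng.standard_normal(30)
    return standardize_columns(np.column_stack([col, col]), ["a", "b"])


@pytest.fixture
def standardized_response():
    def make(n, seed=99):
        r = np.random.default_rng(seed)
        y = r.standard_normal(n)
        return (y - y.mean()) / y.std(ddof=1)

    return make
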