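import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_rating_matrix_with_f(f_ratio: float, n: int = 65, k: int = 2) -> np.ndarray:
    """Construct an (n x k=2) rating matrix whose one-way ANOVA F equals f_ratio.

    Rows are (m_i - d/2, m_i + d/2) with constant within-pair spread d chosen
    so MSW = 1, and row centers scaled so MSB = f_ratio.
    """
    assert k == 2
    d = np.sqrt(2.0)  # within mean square = d^2 / 2 = 1
    m = np.arange(n, dtype=float)
    m -= m.mean()
    m *= np.sqrt(f_ratio / 2.0 / (m @ m / (n - 1)))
    return np.column_stack([m - d / 2.0, m + d / 2.0])
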