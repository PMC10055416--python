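import numpy as np
import pytest

from bcfinemap.data import SummaryStats


def random_correlation(m: int, rng: np.random.Generator) -> np.ndarray:
    """Random SPD correlation matrix via a wide Wishart-style factor."""
    B = rng.standard_normal((m, m + 10))
    C = B @ B.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def random_stats(m: int, rng: np.random.Generator, n: int = 5000) -> SummaryStats:
    return SummaryStats(
        z=rng.standard_normal(m), ld=random_correlation(m, rng), n=n
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
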