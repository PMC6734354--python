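import numpy as np
import pytest

from richrv.types import RRSeries


def rr_from_values(rr_ms, start_s=0.0):
    """Build a consistent RRSeries from interval values alone."""
    rr_ms = np.asarray(rr_ms, dtype=float)
    times = start_s + np.cumsum(rr_ms) / 1000.0
    return RRSeries(times, rr_ms)


def random_rr(rng, n=None):
    """A physiologically plausible random tachogram for oracle comparisons."""
    if n is None:
        n = int(rng.integers(10, 400))
    vals = rng.uniform(500.0, 1200.0, size=n)
    return rr_from_values(vals)


@pytest.fixture
def toy_rr():
    """The worked five-interval example used throughout the docs."""
    return rr_from_values([800.0, 860.0, 820.0, 900.0, 840.0])


@pytest.fixture
def constant_rr():
    return rr_from_values(np.full(300, 1000.0))
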