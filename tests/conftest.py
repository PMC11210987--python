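import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_series(rng, n_min=2, n_max=12, t_max=600, low=20.0, high=80.0):
    """Random sorted (times, values) series for fuzzing the eGFR detectors."""
    n = int(rng.integers(n_min, n_max + 1))
    times = np.sort(rng.integers(0, t_max, size=n)).astype(float)
    values = rng.uniform(low, high, size=n)
    return times, values


def random_creatinine_series(rng, n_min=2, n_max=12):
    """Random series on the creatinine scale with occasional spikes."""
    n = int(rng.integers(n_min, n_max + 1))
    times = np.sort(rng.choice(np.arange(0, 40), size=n, replace=False)).astype(float)
    values = rng.uniform(50.0, 120.0, size=n)
    spikes = rng.uniform(size=n) < 0.25
    values[spikes] *= rng.uniform(1.2, 2.5, size=int(spikes.sum()))
    return times, values
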