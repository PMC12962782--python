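import numpy as np
import pytest

from cholinepipe.types import SpikeTrain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def regular_train():
    """Perfectly regular 10 ms spacing, 3 spikes — exhaustive pair case."""
    return SpikeTrain("reg3", np.array([0.0, 0.010, 0.020]), 0.0, 1.0)


def brute_force_acg_counts(times, bin_width, max_lag):
    """O(n^2) pairwise-lag histogram, the independent ACG oracle."""
    times = np.asarray(times, dtype=float)
    n_bins = int(round(max_lag / bin_width))
    counts = np.zeros(n_bins, dtype=np.int64)
    chunk = 2000
    for i0 in range(0, len(times), chunk):
        block = times[i0 : i0 + chunk]
        diffs = times[None, :] - block[:, None]
        lags = diffs[diffs > 0]
        lags = lags[lags < max_lag]
        bins = (lags / bin_width).astype(np.int64)
        bins = bins[bins < n_bins]
        np.add.at(counts, bins, 1)
    return counts
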