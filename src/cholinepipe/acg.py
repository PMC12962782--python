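"""Autocorrelogram (ACG) statistics and firing-pattern classification.

The ACG is the histogram of positive lags between all distinct spike
pairs of one unit, computed at 0.5 ms resolution and normalized to its
mean.  Three scalar statistics summarise it:

* **Burst Index** — contrast between the short-lag maximum (0–25 ms)
  and the long-lag mean (180–200 ms), normalized by the larger of the
  two, hence in [-1, 1].  Bursting units pile pair mass at short lags.
* **Theta Index** — the same style of contrast between the mean around
  the 5–10 Hz peak (±25 ms around the maximum in the 100–200 ms lag
  band) and symmetric flanking bands; positive for theta-rhythmic units.
* **Relative refractory period** — the lag at which a 10 ms-smoothed
  ACG recovers to half the distance between its central trough and its
  long-lag asymptote.  A functional measure, not a biophysical one.

Units are classified into strongly-bursting (Burst-SB), Poisson-like
bursting (Burst-PL) and regular-rhythmic (Reg) phenotypes from these
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .types import SpikeTrain, ValidationError

__all__ = [
    "Autocorrelogram",
    "FiringPatternCall",
    "compute_acg",
    "smooth_acg",
    "burst_index",
    "theta_index",
    "refractory_period",
    "classify_firing_pattern",
]


@dataclass(frozen=True)
class Autocorrelogram:
    """One-sided binned lag histogram of a spike train.

    ``lags`` are bin centers (s) of half-open bins
    ``[k*bin_width, (k+1)*bin_width)`` for k = 0, 1, ...; zero-lag
    self-pairs are excluded by construction (only distinct ordered
    pairs with positive lag enter).  ``norm`` is ``counts`` divided by
    its mean over all bins up to ``max_lag``.
    """

    lags: np.ndarray
    counts: np.ndarray
    norm: np.ndarray
    bin_width: float
    n_spikes_used: int
    smoothing: str = "none"

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.counts) < 0):
            raise ValidationError("ACG counts must be non-negative")
        if np.any(np.diff(self.lags) <= 0):
            raise ValidationError("ACG lags must be strictly increasing")

    @property
    def max_lag(self) -> float:
        return float(self.lags[-1] + self.bin_width / 2)

    def window_slice(self, lo: float, hi: float) -> np.ndarray:
        """Indices of bins whose centers fall in the half-open [lo, hi)."""
        idx = np.flatnonzero((self.lags >= lo) & (self.lags < hi))
        if idx.size == 0:
            raise ValidationError(f"ACG does not cover window [{lo}, {hi})")
        return idx


@dataclass(frozen=True)
class FiringPatternCall:
    burst_index: float
    theta_index: float
    refractory_s: float
    label: str  # Burst-SB | Burst-PL | Reg | unclassifiable


def compute_acg(
    train: SpikeTrain,
    bin_width: float = 0.0005,
    max_lag: float = 0.5,
    spike_cap: int = 50_000,
) -> Autocorrelogram:
    """Compute the one-sided autocorrelogram of a spike train.

    ``counts[k]`` is the number of ordered distinct spike pairs
    ``(i, j), i < j`` whose lag ``t_j - t_i`` falls in bin k.  Units
    with more than ``spike_cap`` spikes use exactly the first
    ``spike_cap`` spikes by time (memory guard for very active units).
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    if max_lag < 10 * bin_width:
        raise ValidationError("max_lag must be at least 10 bin widths")
    if spike_cap < 2:
        raise ValidationError("spike_cap must be >= 2")
    if train.n_spikes < 2:
        raise ValidationError(f"unit {train.unit_id}: insufficient spikes for ACG")

    times = train.times[:spike_cap]
    n = times.size
    n_bins = int(round(max_lag / bin_width))
    counts = np.zeros(n_bins, dtype=np.int64)
    # For each spike, histogram lags to all later spikes within max_lag.
    # The search bound overshoots by one bin; the bin filter below is
    # what decides inclusion, so float rounding at the boundary cannot
    # drop pairs whose computed lag lands just inside the last bin.
    hi = np.searchsorted(times, times + max_lag + bin_width, side="right")
    for i in range(n - 1):
        lags = times[i + 1 : hi[i]] - times[i]
        if lags.size:
            bins = (lags / bin_width).astype(np.int64)
            bins = bins[bins < n_bins]
            np.add.at(counts, bins, 1)
    lags = (np.arange(n_bins) + 0.5) * bin_width
    mean = counts.mean()
    norm = counts / mean if mean > 0 else counts.astype(float)
    return Autocorrelogram(
        lags=lags,
        counts=counts,
        norm=norm,
        bin_width=bin_width,
        n_spikes_used=n,
    )


def _moving_average(values: np.ndarray, npts: int) -> np.ndarray:
    """Centered moving average; edges shrink to the valid overlap."""
    kernel = np.ones(npts)
    summed = np.convolve(values, kernel, mode="same")
    weight = np.convolve(np.ones_like(values), kernel, mode="same")
    return summed / weight


def smooth_acg(acg: Autocorrelogram, window: float = 0.0025) -> Autocorrelogram:
    """Smooth an ACG with a centered moving average of width ``window``.

    ``window`` must be an odd multiple of the bin width (e.g. 2.5 ms for
    five 0.5 ms bins).  Edges use shrunken windows (mean of available
    points) so no artificial trough is introduced at lag zero.
    """
    ratio = window / acg.bin_width
    npts = int(round(ratio))
    if abs(ratio - npts) > 1e-9 or npts % 2 != 1:
        raise ValidationError(
            f"smoothing window {window} must be an odd multiple of bin width"
        )
    return replace(
        acg,
        counts=_moving_average(acg.counts.astype(float), npts),
        norm=_moving_average(acg.norm, npts),
        smoothing=f"moving_average_{npts}pt",
    )


def burst_index(
    acg: Autocorrelogram,
    burst_win: tuple[float, float] = (0.0, 0.025),
    base_win: tuple[float, float] = (0.180, 0.200),
) -> float:
    """Burst Index: (max over 0-25 ms - mean over 180-200 ms) / max(the two).

    Returns 0 when both terms are 0 (degenerate empty ACG windows).
    The normalization keeps the index in [-1, 1] and cancels any global
    rescaling of the ACG.
    """
    if burst_win[1] > base_win[0] and base_win[1] > burst_win[0]:
        raise ValidationError("burst and baseline windows overlap")
    max_burst = float(np.max(acg.norm[acg.window_slice(*burst_win)]))
    mean_base = float(np.mean(acg.norm[acg.window_slice(*base_win)]))
    denom = max(max_burst, mean_base)
    if denom == 0:
        return 0.0
    return (max_burst - mean_base) / denom


def theta_index(
    acg: Autocorrelogram,
    search_win: tuple[float, float] = (0.100, 0.200),
    peak_halfwidth: float = 0.025,
    flank_wins: tuple[tuple[float, float], ...] = ((0.050, 0.075), (0.225, 0.250)),
) -> float:
    """Theta Index: contrast of the 5-10 Hz ACG peak against flanking bands.

    The peak is the lag of the ACG maximum within ``search_win``
    (100-200 ms, i.e. 5-10 Hz); the peak term is the mean over
    ``peak ± peak_halfwidth`` and the reference term the mean over the
    flanking windows.  Same max-normalization as the Burst Index, so
    the result lies in [-1, 1].
    """
    search = acg.window_slice(*search_win)
    peak_lag = float(acg.lags[search[np.argmax(acg.norm[search])]])
    peak_idx = acg.window_slice(peak_lag - peak_halfwidth, peak_lag + peak_halfwidth)
    mean_peak = float(np.mean(acg.norm[peak_idx]))
    flank_idx = np.concatenate([acg.window_slice(*w) for w in flank_wins])
    mean_flank = float(np.mean(acg.norm[flank_idx]))
    denom = max(mean_peak, mean_flank)
    if denom == 0:
        return 0.0
    return (mean_peak - mean_flank) / denom


def refractory_period(
    acg: Autocorrelogram,
    trough_smooth: float = 0.010,
    asymptote_win: tuple[float, float] = (0.180, 0.200),
) -> float:
    """Relative refractory period from the ACG's central trough.

    The ACG is smoothed with a ``trough_smooth`` (10 ms) moving
    average; the trough value is the smoothed value at the smallest
    lag, the asymptote the mean over ``asymptote_win``.  The refractory
    period is the smallest lag at which the smoothed ACG reaches the
    half-height between trough and asymptote; 0 when the trough is not
    below the asymptote.
    """
    if acg.bin_width > 0.001:
        raise ValidationError("refractory estimation needs bin_width <= 1 ms")
    if not np.any(acg.norm > 0):
        raise ValidationError("degenerate ACG: all bins zero")
    npts = int(round(trough_smooth / acg.bin_width))
    if npts % 2 == 0:
        npts += 1
    smoothed = _moving_average(acg.norm, npts)
    trough = smoothed[0]
    height = float(np.mean(smoothed[acg.window_slice(*asymptote_win)]))
    if trough >= height:
        return 0.0
    level = trough + 0.5 * (height - trough)
    above = np.flatnonzero(smoothed >= level)
    if above.size == 0:
        return float(acg.max_lag)
    return float(acg.lags[above[0]])


def classify_firing_pattern(
    bi: float,
    ti: float,
    refractory_s: float,
    reg_refractory_min: float = 0.040,
    sb_burst_index_min: float = 0.4,
) -> FiringPatternCall:
    """Classify a unit from its ACG statistics.

    Default rule: regular-rhythmic (Reg) when the refractory period is
    long (>= 40 ms) and the Theta Index positive; otherwise
    strongly-bursting (Burst-SB) when the Burst Index >= 0.4, else
    Poisson-like (Burst-PL).  The boundaries are configuration values,
    not study-reported constants.
    """
    if not (np.isfinite(bi) and np.isfinite(ti) and np.isfinite(refractory_s)):
        label = "unclassifiable"
    elif refractory_s >= reg_refractory_min and ti > 0:
        label = "Reg"
    elif bi >= sb_burst_index_min:
        label = "Burst-SB"
    else:
        label = "Burst-PL"
    return FiringPatternCall(
        burst_index=bi, theta_index=ti, refractory_s=refractory_s, label=label
    )
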