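"""Intrinsic-excitability metrics from current-step voltage sweeps.

From each 1 s positive current step: spike detection by threshold
crossing, spike delay (step onset to first action-potential peak),
burst frequency from the three interspike intervals that follow the
first spike, and an evoked autocorrelogram pooled over sweeps (no
cross-sweep pairs) smoothed with a 5 ms moving average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acg import Autocorrelogram, smooth_acg
from .types import SpikeTrain, ValidationError

__all__ = [
    "VoltageSweep",
    "detect_spikes",
    "spike_delay",
    "burst_frequency",
    "evoked_acg",
    "NoSpikeResult",
]


class NoSpikeResult:
    """Sentinel for sweeps without the spikes a metric requires."""

    def __init__(self, reason: str) -> None:
        self.reason = reason

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"NoSpikeResult({self.reason!r})"


@dataclass(frozen=True)
class VoltageSweep:
    """One current-clamp sweep: time (s), voltage (mV), step timing."""

    t: np.ndarray
    v: np.ndarray
    step_onset: float
    step_offset: float
    step_amplitude: float = np.nan  # pA

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if len(v) != len(t):
            raise ValidationError("voltage length does not match time grid")
        dt = np.diff(t)
        if np.any(np.abs(dt - dt[0]) > 1e-9):
            raise ValidationError("time grid is not uniform")
        if not (t[0] <= self.step_onset < self.step_offset <= t[-1]):
            raise ValidationError("step must lie within the sweep span")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


def detect_spikes(
    sweep: VoltageSweep,
    threshold_mv: float = -20.0,
    min_isi: float = 0.001,
) -> np.ndarray:
    """Action-potential peak times from upward threshold crossings.

    Each upward crossing of ``threshold_mv`` contributes the time of
    the local voltage maximum before the trace falls back below
    threshold; events closer than ``min_isi`` are merged (the larger
    peak wins).
    """
    if sweep.fs < 10_000:
        raise ValidationError("need at least 10 kHz sampling for spike detection")
    v = sweep.v
    above = v >= threshold_mv
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    offsets = np.flatnonzero(~above[1:] & above[:-1]) + 1
    peaks = []
    for on in onsets:
        off_candidates = offsets[offsets > on]
        off = off_candidates[0] if off_candidates.size else len(v)
        seg = slice(on, off)
        peaks.append(on + int(np.argmax(v[seg])))
    if not peaks:
        return np.empty(0)
    times = sweep.t[np.asarray(peaks)]
    amps = v[np.asarray(peaks)]
    merged_t, merged_a = [times[0]], [amps[0]]
    for t_i, a_i in zip(times[1:], amps[1:]):
        if t_i - merged_t[-1] < min_isi:
            if a_i > merged_a[-1]:
                merged_t[-1], merged_a[-1] = t_i, a_i
        else:
            merged_t.append(t_i)
            merged_a.append(a_i)
    return np.asarray(merged_t)


def spike_delay(sweep: VoltageSweep, spikes: np.ndarray) -> float | NoSpikeResult:
    """Interval from step onset to the first action-potential peak (s)."""
    in_step = spikes[(spikes >= sweep.step_onset) & (spikes < sweep.step_offset)]
    if in_step.size == 0:
        return NoSpikeResult("no spike within the current step")
    return float(in_step[0] - sweep.step_onset)


def burst_frequency(spikes: np.ndarray) -> float | NoSpikeResult:
    """Firing frequency from the three ISIs after the first spike (Hz).

    Equals ``1 / mean(ISI_1..3)`` which is algebraically
    ``3 / (t4 - t1)`` for the first four spike times.
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size < 4:
        return NoSpikeResult("fewer than 4 spikes in the step")
    isis = np.diff(spikes[:4])
    return float(1.0 / isis.mean())


def evoked_acg(
    sweeps_spikes: list[np.ndarray],
    bin_width: float = 0.0005,
    max_lag: float = 0.5,
    smoothing: float = 0.005,
) -> Autocorrelogram:
    """ACG of step-evoked spikes, pooled over sweeps.

    Per-sweep pair counts are summed (spikes are never paired across
    sweeps), mean-normalized, and smoothed with a ``smoothing`` (5 ms)
    moving average.
    """
    total = sum(len(s) for s in sweeps_spikes)
    if total < 2:
        raise ValidationError("insufficient spikes across sweeps")
    n_bins = int(round(max_lag / bin_width))
    counts = np.zeros(n_bins, dtype=np.int64)
    for spikes in sweeps_spikes:
        spikes = np.asarray(spikes, dtype=float)
        for i in range(len(spikes) - 1):
            lags = spikes[i + 1 :] - spikes[i]
            lags = lags[lags < max_lag]
            if lags.size:
                np.add.at(counts, (lags / bin_width).astype(np.int64), 1)
    lags = (np.arange(n_bins) + 0.5) * bin_width
    mean = counts.mean()
    norm = counts / mean if mean > 0 else counts.astype(float)
    acg = Autocorrelogram(
        lags=lags, counts=counts, norm=norm, bin_width=bin_width, n_spikes_used=total
    )
    # moving averages need an odd point count; a nominal 5 ms window over
    # 0.5 ms bins (10 points) rounds up to the nearest odd (11 points)
    npts = int(round(smoothing / bin_width))
    if npts % 2 == 0:
        npts += 1
    return smooth_acg(acg, npts * bin_width)


def make_step_sweep(
    spike_times: np.ndarray,
    step_onset: float = 0.5,
    step_dur: float = 1.0,
    fs: float = 20_000.0,
    total_dur: float = 2.5,
    rest_mv: float = -60.0,
    peak_mv: float = 30.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> VoltageSweep:
    """Construct a synthetic voltage sweep with triangular APs at given times.

    A test/fixture helper: 2 ms-wide triangular spikes rising to
    ``peak_mv`` are superimposed on a resting potential with optional
    Gaussian noise.  Synthetic stand-in for recorded sweeps.
    """
    rng = np.random.default_rng(seed)
    n = int(round(total_dur * fs))
    t = np.arange(n) / fs
    v = np.full(n, rest_mv)
    half_w = 0.001  # 1 ms rise, 1 ms fall
    for st in np.asarray(spike_times, dtype=float):
        idx = (np.abs(t - st) < half_w)
        v[idx] = np.maximum(
            v[idx], rest_mv + (peak_mv - rest_mv) * (1 - np.abs(t[idx] - st) / half_w)
        )
    if noise_sd > 0:
        v = v + rng.normal(0, noise_sd, size=n)
    return VoltageSweep(
        t=t, v=v, step_onset=step_onset, step_offset=step_onset + step_dur
    )
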