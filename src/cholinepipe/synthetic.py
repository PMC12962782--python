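"""Ground-truth synthetic data generators.

Each generator emulates one statistical structure the analyses assume —
bursting / Poisson / regular-rhythmic point processes, event-locked rate
modulation, two-channel photometry with shared motion artifact and
bleaching, lag-coupled signal pairs, pupil traces lagging calcium — and
returns its hidden parameters in a :class:`SyntheticGroundTruth` so
recovery can be asserted.  Every generator is bit-reproducible from
(name, parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .types import (
    CalciumSignal,
    EventSeries,
    PhotometrySession,
    PupilLandmarks,
    SpikeTrain,
    TrialTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticGroundTruth",
    "gen_poisson_train",
    "gen_bursting_train",
    "gen_regular_theta_train",
    "gen_task_session",
    "gen_photometry",
    "gen_coupled_pair",
    "gen_pupil_coupled",
    "gen_pupil_landmarks",
]


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Hidden parameters of a generated dataset."""

    generator: str
    seed: int
    params: dict[str, Any] = field(default_factory=dict)


def _dedupe(times: np.ndarray, min_gap: float = 1e-4) -> np.ndarray:
    """Enforce strictly increasing times by dropping too-close spikes."""
    if times.size < 2:
        return times
    keep = [0]
    for i in range(1, times.size):
        if times[i] - times[keep[-1]] >= min_gap:
            keep.append(i)
    return times[keep]


def gen_poisson_train(
    rate: float,
    duration: float,
    dead_time: float = 0.0,
    seed: int = 0,
    unit_id: str = "poisson",
) -> tuple[SpikeTrain, SyntheticGroundTruth]:
    """Homogeneous Poisson spike train with an absolute dead time.

    Spikes are laid down sequentially: each inter-spike interval is
    ``dead_time`` plus an Exponential(rate) gap, so the minimum ISI is
    exactly ``dead_time`` and the realized rate is approximately
    ``rate / (1 + rate * dead_time)``.
    """
    if rate <= 0:
        raise ValidationError("rate must be positive")
    if dead_time < 0:
        raise ValidationError("dead_time must be non-negative")
    if rate * dead_time >= 1:
        raise ValidationError("unrealizable: rate * dead_time >= 1")
    rng = np.random.default_rng(seed)
    n_max = int(rate * duration * 2 + 100)
    gaps = dead_time + rng.exponential(1.0 / rate, size=n_max)
    times = np.cumsum(gaps)
    while times.size and times[-1] < duration:  # pragma: no cover - rare top-up
        extra = dead_time + rng.exponential(1.0 / rate, size=n_max)
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    times = times[times < duration]
    truth = SyntheticGroundTruth(
        "poisson_train", seed, {"rate": rate, "duration": duration, "dead_time": dead_time}
    )
    return SpikeTrain(unit_id, times, 0.0, duration), truth


def gen_bursting_train(
    burst_rate: float = 0.3,
    spikes_per_burst: tuple[int, int] = (3, 6),
    intra_isi: float = 0.006,
    duration: float = 600.0,
    seed: int = 0,
    isi_jitter: float = 0.1,
    unit_id: str = "bursting",
) -> tuple[SpikeTrain, SyntheticGroundTruth]:
    """Bursting spike train: Poisson burst onsets, short intra-burst ISIs.

    Burst onsets follow a Poisson process at ``burst_rate``; each burst
    carries k spikes (k uniform over ``spikes_per_burst`` inclusive)
    separated by ``intra_isi`` with ±``isi_jitter`` fractional uniform
    jitter.  Overlapping bursts are merged by the global dedupe pass.
    """
    lo, hi = spikes_per_burst
    if burst_rate < 0:
        raise ValidationError("burst_rate must be >= 0")
    if burst_rate > 0 and burst_rate * hi * intra_isi > 0.5:
        raise ValidationError("burst parameters too dense: bursts would merge")
    rng = np.random.default_rng(seed)
    if burst_rate == 0:
        times = np.empty(0)
    else:
        n_bursts = rng.poisson(burst_rate * duration)
        onsets = np.sort(rng.uniform(0, duration, size=n_bursts))
        ks = rng.integers(lo, hi + 1, size=n_bursts)
        spikes = []
        for onset, k in zip(onsets, ks):
            gaps = intra_isi * (1 + isi_jitter * rng.uniform(-1, 1, size=k - 1))
            spikes.append(onset + np.concatenate([[0.0], np.cumsum(gaps)]))
        times = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
        n_before = times.size
        times = _dedupe(times)
        if times.size < n_before:
            logger.info("merged %d overlapping burst spikes", n_before - times.size)
        times = times[times < duration]
    truth = SyntheticGroundTruth(
        "bursting_train",
        seed,
        {
            "burst_rate": burst_rate,
            "spikes_per_burst": spikes_per_burst,
            "intra_isi": intra_isi,
            "isi_jitter": isi_jitter,
            "duration": duration,
        },
    )
    return SpikeTrain(unit_id, times, 0.0, duration), truth


def gen_regular_theta_train(
    rate: float = 4.0,
    dead_time: float = 0.060,
    theta_hz: float = 7.0,
    depth: float = 0.8,
    duration: float = 900.0,
    seed: int = 0,
    unit_id: str = "regular",
) -> tuple[SpikeTrain, SyntheticGroundTruth]:
    """Regular-rhythmic train: theta-modulated Poisson with a long dead time.

    Inhomogeneous Poisson with
    ``rate(t) = rate * (1 + depth * cos(2*pi*theta_hz*t))`` realized by
    thinning, then sequentially thinned by the absolute dead time so the
    minimum ISI equals ``dead_time``.
    """
    if not 0 <= depth <= 1:
        raise ValidationError("depth must be in [0, 1]")
    if rate <= 0:
        raise ValidationError("rate must be positive")
    if rate * dead_time >= 1:
        raise ValidationError("unrealizable: rate * dead_time >= 1")
    rng = np.random.default_rng(seed)
    rate_max = rate * (1 + depth)
    n_cand = rng.poisson(rate_max * duration)
    cand = np.sort(rng.uniform(0, duration, size=n_cand))
    accept = rng.uniform(0, 1, size=n_cand) < (
        (1 + depth * np.cos(2 * np.pi * theta_hz * cand)) / (1 + depth)
    )
    cand = cand[accept]
    times = _dedupe(cand, min_gap=dead_time) if dead_time > 0 else _dedupe(cand)
    truth = SyntheticGroundTruth(
        "regular_theta_train",
        seed,
        {
            "rate": rate,
            "dead_time": dead_time,
            "theta_hz": theta_hz,
            "depth": depth,
            "duration": duration,
        },
    )
    return SpikeTrain(unit_id, times, 0.0, duration), truth


def _modulated_train(
    rng: np.random.Generator,
    duration: float,
    base_rate: float,
    windows: list[tuple[float, float, float]],
) -> np.ndarray:
    """Poisson train whose rate is multiplied by `gain` inside windows.

    ``windows`` holds (start, end, gain) triples; gains < 1 model
    suppression.  Realized by thinning from the maximum rate.
    """
    gains = [g for _, _, g in windows]
    rate_max = base_rate * max(1.0, *gains) if gains else base_rate
    n_cand = rng.poisson(rate_max * duration)
    cand = np.sort(rng.uniform(0, duration, size=n_cand))
    local = np.full(cand.size, base_rate)
    for start, end, gain in windows:
        mask = (cand >= start) & (cand < end)
        local[mask] = base_rate * gain
    accept = rng.uniform(0, 1, size=cand.size) < local / rate_max
    return _dedupe(cand[accept])


def gen_task_session(
    n_trials: int = 100,
    cue_probs: dict[int, dict[str, float]] | None = None,
    outcome_delay: tuple[float, float] = (0.4, 0.6),
    response_spec: dict[str, dict[str, float]] | None = None,
    base_rate: float = 10.0,
    iti: tuple[float, float] = (5.0, 9.0),
    seed: int = 0,
) -> tuple[TrialTable, dict[str, EventSeries], dict[str, SpikeTrain], SyntheticGroundTruth]:
    """Simulate a conditioning session: trials, events, responsive units.

    The task: on each trial one of two cues sounds; after a 0.4-0.6 s
    delay the scheduled outcome (water reward, air-puff punishment, or
    omission) is delivered.  ``cue_probs`` maps cue id to outcome
    probabilities (default: cue 1 -> 90% reward / 10% omission, cue 2 ->
    90% punishment / 10% omission, matching the task contingencies).

    ``response_spec`` maps unit_id to a dict with keys ``event`` (e.g.
    "reward"), ``latency``, ``duration`` (s) and ``gain`` (rate
    multiplier; < 1 is suppression).  Units fire Poisson at
    ``base_rate`` outside response windows.
    """
    if cue_probs is None:
        cue_probs = {
            1: {"reward": 0.9, "omission": 0.1},
            2: {"punishment": 0.9, "omission": 0.1},
        }
    for cue_id, probs in cue_probs.items():
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValidationError(f"cue {cue_id}: outcome probabilities must sum to 1")
    response_spec = response_spec or {}
    rng = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed)
    unit_seeds = ss.spawn(max(len(response_spec), 1))

    cue_ids = rng.choice(sorted(cue_probs), size=n_trials)
    cue_times = np.cumsum(rng.uniform(*iti, size=n_trials)) + 5.0
    rows = []
    for cue_t, cue_id in zip(cue_times, cue_ids):
        probs = cue_probs[int(cue_id)]
        outcome = rng.choice(list(probs), p=list(probs.values()))
        delay = rng.uniform(*outcome_delay)
        rows.append(
            {
                "cue_time": cue_t,
                "cue_id": int(cue_id),
                "outcome_time": np.nan if outcome == "omission" else cue_t + delay,
                "outcome": outcome,
            }
        )
    trials = TrialTable(pd.DataFrame(rows))
    duration = float(cue_times[-1] + 10.0)

    events = {
        label: trials.events(label) for label in ("cue1", "cue2", "reward", "punishment")
    }

    trains: dict[str, SpikeTrain] = {}
    for (unit_id, spec), child in zip(sorted(response_spec.items()), unit_seeds):
        ev = events[spec["event"]] if spec["event"] in events else trials.events(spec["event"])
        windows = [
            (t + spec["latency"], t + spec["latency"] + spec["duration"], spec["gain"])
            for t in ev.times
        ]
        unit_rng = np.random.default_rng(child)
        times = _modulated_train(unit_rng, duration, spec.get("base_rate", base_rate), windows)
        trains[unit_id] = SpikeTrain(unit_id, times, 0.0, duration)

    truth = SyntheticGroundTruth(
        "task_session",
        seed,
        {
            "n_trials": n_trials,
            "cue_probs": cue_probs,
            "outcome_delay": outcome_delay,
            "base_rate": base_rate,
            "response_spec": response_spec,
            "duration": duration,
        },
    )
    return trials, events, trains, truth


def _gcamp_kernel(fs: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Double-exponential calcium transient kernel, peak-normalized to 1."""
    t = np.arange(0, 5 * tau_decay, 1.0 / fs)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return k / k.max()


def gen_photometry(
    duration: float = 300.0,
    fs: float = 100.0,
    transient_times: np.ndarray | None = None,
    n_transients: int = 20,
    amplitudes: float | np.ndarray = 4.0,
    tau_rise: float = 0.05,
    tau_decay: float = 0.6,
    artifact_sd: float = 0.5,
    bleach_tau: float = 600.0,
    noise_sd: float = 0.05,
    baseline: float = 100.0,
    seed: int = 0,
) -> tuple[PhotometrySession, SyntheticGroundTruth]:
    """Two-channel photometry with shared artifact, bleaching and transients.

    The isosbestic channel is ``f405 = baseline * bleach(t) + artifact +
    noise``; the calcium channel adds GCaMP-like transients (double-
    exponential kernel, ``tau_rise`` 50 ms / ``tau_decay`` 600 ms by
    default) at the given times with amplitudes in percent of baseline.
    The motion artifact is a mean-reverting random walk shared by both
    channels; ``bleach_tau`` sets the exponential photobleaching decay.
    The ground truth stores the clean percent-transient trace.
    """
    if baseline <= 0 or noise_sd < 0:
        raise ValidationError("negative fluorescence configured")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    bleach = np.exp(-t / bleach_tau) if np.isfinite(bleach_tau) else np.ones(n)

    # AR(1) mean-reverting walk: slow shared motion/autofluorescence drift.
    if artifact_sd > 0:
        steps = rng.normal(0, 1, size=n)
        artifact = np.empty(n)
        artifact[0] = 0.0
        phi = 1 - 1.0 / (2.0 * fs)  # ~2 s reversion time constant
        for i in range(1, n):
            artifact[i] = phi * artifact[i - 1] + steps[i]
        artifact *= artifact_sd / max(artifact.std(), 1e-12)
    else:
        artifact = np.zeros(n)

    if transient_times is None:
        transient_times = np.sort(
            rng.uniform(5.0, duration - 5.0, size=n_transients)
        )
    else:
        transient_times = np.asarray(transient_times, dtype=float)
    amplitudes = np.broadcast_to(
        np.asarray(amplitudes, dtype=float), transient_times.shape
    ).copy()

    clean = np.zeros(n)  # transient trace in percent of baseline
    kernel = _gcamp_kernel(fs, tau_rise, tau_decay)
    for t0, amp in zip(transient_times, amplitudes):
        i0 = int(round(t0 * fs))
        seg = kernel[: n - i0]
        clean[i0 : i0 + seg.size] += amp * seg

    f405 = baseline * bleach + artifact + rng.normal(0, noise_sd, size=n)
    f465 = (
        baseline * bleach * (1 + clean / 100.0)
        + artifact
        + rng.normal(0, noise_sd, size=n)
    )
    session = PhotometrySession(t=t, f465=f465, f405=f405, fs=fs)
    truth = SyntheticGroundTruth(
        "photometry",
        seed,
        {
            "transient_times": transient_times,
            "amplitudes": amplitudes,
            "tau_rise": tau_rise,
            "tau_decay": tau_decay,
            "artifact_sd": artifact_sd,
            "bleach_tau": bleach_tau,
            "noise_sd": noise_sd,
            "baseline": baseline,
            "clean_dff": clean,
            "artifact": artifact,
        },
    )
    return session, truth


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, tau: float = 0.3) -> np.ndarray:
    """Ornstein-Uhlenbeck-style smooth noise, unit variance."""
    phi = np.exp(-1.0 / (fs * tau))
    x = np.empty(n)
    x[0] = rng.normal()
    eps = rng.normal(0, 1, size=n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + np.sqrt(1 - phi**2) * eps[i]
    return x


def gen_coupled_pair(
    duration: float = 120.0,
    fs: float = 100.0,
    lag: float = 0.8,
    gain: float = 1.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[CalciumSignal, CalciumSignal, SyntheticGroundTruth]:
    """Lag-coupled signal pair: y = gain * x(t - lag) + independent noise.

    Emulates coordinated calcium activity in two regions driven by a
    common source with a transmission lag.  ``lag`` is rounded to the
    nearest sample; the value used is recorded in the ground truth.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    lag_samples = int(round(lag * fs))
    if abs(lag_samples) >= n:
        raise ValidationError("lag exceeds signal length")
    x = _smooth_noise(rng, n + abs(lag_samples), fs)
    y_full = gain * np.roll(x, lag_samples)
    if gain == 0:
        y_full = _smooth_noise(rng, n + abs(lag_samples), fs)
    start = abs(lag_samples)
    t = np.arange(n) / fs
    xs = x[start : start + n]
    ys = y_full[start : start + n] + noise_sd * rng.normal(0, 1, size=n)
    truth = SyntheticGroundTruth(
        "coupled_pair",
        seed,
        {
            "lag": lag_samples / fs,
            "lag_requested": lag,
            "gain": gain,
            "noise_sd": noise_sd,
            "fs": fs,
        },
    )
    return (
        CalciumSignal(t=t, dff=xs, fs=fs, provenance={"synthetic": True}),
        CalciumSignal(t=t, dff=ys, fs=fs, provenance={"synthetic": True}),
        truth,
    )


def gen_pupil_coupled(
    calcium: CalciumSignal,
    pupil_lag: float = 0.7,
    smoothing_tau: float = 0.5,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Pupil-diameter series that lags the calcium signal.

    The pupil is a low-pass-filtered (single-pole, ``smoothing_tau``),
    lagged copy of the calcium trace plus independent noise, so
    information flows calcium -> pupil by construction.
    """
    if pupil_lag < 0:
        raise ValidationError("pupil_lag must be >= 0")
    rng = np.random.default_rng(seed)
    fs = calcium.fs
    lag_samples = int(round(pupil_lag * fs))
    shifted = np.concatenate(
        [np.full(lag_samples, calcium.dff[0]), calcium.dff[: len(calcium.dff) - lag_samples]]
    )
    if smoothing_tau > 0:
        alpha = 1 - np.exp(-1.0 / (fs * smoothing_tau))
        pupil = np.empty_like(shifted)
        pupil[0] = shifted[0]
        for i in range(1, len(shifted)):
            pupil[i] = pupil[i - 1] + alpha * (shifted[i] - pupil[i - 1])
    else:
        pupil = shifted.copy()
    pupil = pupil + noise_sd * rng.normal(0, 1, size=len(pupil))
    truth = SyntheticGroundTruth(
        "pupil_coupled",
        seed,
        {
            "pupil_lag": lag_samples / fs,
            "smoothing_tau": smoothing_tau,
            "noise_sd": noise_sd,
        },
    )
    return pupil, truth


def gen_pupil_landmarks(
    t: np.ndarray,
    diameter: np.ndarray,
    center: tuple[float, float] = (120.0, 90.0),
    seed: int = 0,
) -> tuple[PupilLandmarks, SyntheticGroundTruth]:
    """Landmark table whose three diagonal pairs realize a given diameter.

    Places three diameters of a circle of the requested size at random
    but fixed orientations; the mean pair distance equals ``diameter``
    exactly, so the geometry pipeline can be tested end to end.
    """
    rng = np.random.default_rng(seed)
    angles = rng.uniform(0, np.pi, size=3)
    n = len(t)
    pairs = np.empty((n, 3, 2, 2))
    r = np.asarray(diameter, dtype=float) / 2.0
    for i, ang in enumerate(angles):
        dx, dy = np.cos(ang), np.sin(ang)
        pairs[:, i, 0, 0] = center[0] + r * dx
        pairs[:, i, 0, 1] = center[1] + r * dy
        pairs[:, i, 1, 0] = center[0] - r * dx
        pairs[:, i, 1, 1] = center[1] - r * dy
    eyelid = np.zeros((n, 2, 2))
    eyelid[:, 0] = (center[0], center[1] + 40)
    eyelid[:, 1] = (center[0], center[1] - 40)
    truth = SyntheticGroundTruth(
        "pupil_landmarks", seed, {"angles": angles, "center": center}
    )
    return PupilLandmarks(t=np.asarray(t, float), pairs=pairs, eyelid=eyelid), truth
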