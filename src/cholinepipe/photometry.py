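"""Fiber-photometry preprocessing and trial-level response quantification.

The preprocessing chain: zero-phase 20 Hz low-pass on both channels, an
ordinary-least-squares fit of the isosbestic 405 nm channel to the
calcium-dependent 465 nm channel, dF/F = (f465 - f405_fitted) /
f405_fitted x 100, and a zero-phase 0.2 Hz high-pass to remove slow
photobleaching decay.  Trial responses are z-scored against a 2 s
pre-cue baseline (per trial, or against ITI baselines per session) and
quantified by peak, latency, full-width at half maximum and area under
the curve between the half-maximum crossings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .types import CalciumSignal, PhotometrySession, TrialTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseMetrics",
    "TrialPETH",
    "preprocess_dff",
    "zscore_to_baseline",
    "response_metrics",
    "trialwise_cue_test",
]


@dataclass(frozen=True)
class TrialPETH:
    """Per-trial z-scored signal matrix aligned on a trigger."""

    bin_centers: np.ndarray  # s relative to trigger
    matrix: np.ndarray       # trials x samples, z-units
    mean: np.ndarray
    n_trials: int
    fs: float
    excluded_trials: tuple[int, ...] = ()

    def window_slice(self, lo: float, hi: float) -> np.ndarray:
        idx = np.flatnonzero((self.bin_centers >= lo) & (self.bin_centers < hi))
        if idx.size == 0:
            raise ValidationError(f"trial PETH does not cover [{lo}, {hi})")
        return idx


@dataclass(frozen=True)
class ResponseMetrics:
    peak: float       # z-units
    latency: float    # s from trigger
    duration: float   # s, width at half maximum
    auc: float        # z-units * s between half-max crossings
    flag: str = ""


def _sos(kind: str, cutoff_hz: float, fs: float, order: int) -> np.ndarray:
    return signal.butter(order, cutoff_hz, btype=kind, fs=fs, output="sos")


def preprocess_dff(
    session: PhotometrySession,
    lowpass_hz: float = 20.0,
    highpass_hz: float = 0.2,
    filter_order: int = 4,
) -> CalciumSignal:
    """Isosbestic-corrected, band-limited dF/F (percent).

    Steps, in order: (1) zero-phase Butterworth low-pass of both
    channels at ``lowpass_hz``; (2) OLS fit (gain + offset) of the
    low-passed 405 channel to the 465 channel over the whole session;
    (3) dF/F = (f465 - f405_fitted) / f405_fitted x 100; (4) zero-phase
    high-pass at ``highpass_hz`` to remove slow baseline decay.
    """
    if session.duration < 10.0:
        raise ValidationError("session shorter than 10 s")
    if session.fs < 2 * lowpass_hz:
        raise ValidationError(
            f"fs {session.fs} Hz too low for a {lowpass_hz} Hz low-pass"
        )
    if np.allclose(session.f405, 0.0):
        raise ValidationError("isosbestic channel is identically zero")

    lp = _sos("low", lowpass_hz, session.fs, filter_order)
    f465 = signal.sosfiltfilt(lp, session.f465)
    f405 = signal.sosfiltfilt(lp, session.f405)

    if f405.std() < 1e-12 * max(1.0, abs(f405.mean())):
        # constant isosbestic channel: only the gain is identifiable
        gain, offset = f465.mean() / f405.mean(), 0.0
    else:
        gain, offset = np.polyfit(f405, f465, 1)
    f405_fitted = gain * f405 + offset
    if np.any(f405_fitted <= 0):
        raise ValidationError(
            "isosbestic fit nonpositive; check channel scaling or baseline drift "
            "before computing dF/F"
        )
    dff = (f465 - f405_fitted) / f405_fitted * 100.0

    hp = _sos("high", highpass_hz, session.fs, filter_order)
    dff = signal.sosfiltfilt(hp, dff)

    return CalciumSignal(
        t=session.t,
        dff=dff,
        fs=session.fs,
        provenance={
            "lowpass_hz": lowpass_hz,
            "highpass_hz": highpass_hz,
            "filter_order": filter_order,
            "isosbestic_gain": float(gain),
            "isosbestic_offset": float(offset),
        },
    )


def zscore_to_baseline(
    sig: CalciumSignal,
    trials: TrialTable,
    trigger: str = "cue",
    window: tuple[float, float] = (-2.0, 3.0),
    baseline_win: float = 2.0,
    mode: str = "per_trial",
) -> TrialPETH:
    """Align the dF/F trace on a trigger and z-score against baseline.

    ``mode="per_trial"``: each trial is z-scored by the mean and SD of
    its own ``baseline_win`` seconds before the trigger; trials with
    zero baseline SD are excluded with a warning.  ``mode="session"``:
    the whole trace is z-scored once by the pooled statistics of all
    pre-trigger baseline (ITI) windows, then sliced per trial.
    """
    trig_times = trials.events(trigger).times
    pre, post = window
    if baseline_win > -pre:
        raise ValidationError("baseline window must fit inside the trial window")
    n_pre = int(round(-pre * sig.fs))
    n_post = int(round(post * sig.fs))
    n_base = int(round(baseline_win * sig.fs))

    rows, kept, excluded = [], [], []
    trig_idx = np.round((trig_times - sig.t[0]) * sig.fs).astype(int)
    for k, idx in enumerate(trig_idx):
        if idx - n_pre < 0 or idx + n_post > len(sig.dff):
            raise ValidationError(f"trial {k}: baseline/response window outside recording")
        rows.append(sig.dff[idx - n_pre : idx + n_post])
        kept.append(k)
    matrix = np.asarray(rows, dtype=float)
    rel = (np.arange(-n_pre, n_post) + 0.5) / sig.fs

    base_cols = np.flatnonzero((rel >= -baseline_win) & (rel < 0))
    if mode == "per_trial":
        mu = matrix[:, base_cols].mean(axis=1, keepdims=True)
        sd = matrix[:, base_cols].std(axis=1, ddof=0, keepdims=True)
        good = sd[:, 0] > 0
        if not good.all():
            excluded = [kept[i] for i in np.flatnonzero(~good)]
            logger.warning("excluded %d trial(s) with zero baseline SD", len(excluded))
        matrix = (matrix[good] - mu[good]) / sd[good]
    elif mode == "session":
        pooled = matrix[:, base_cols].ravel()
        mu, sd = pooled.mean(), pooled.std(ddof=0)
        if sd == 0:
            raise ValidationError("session baseline SD is zero")
        matrix = (matrix - mu) / sd
    else:
        raise ValidationError(f"unknown z-scoring mode {mode!r}")

    return TrialPETH(
        bin_centers=rel,
        matrix=matrix,
        mean=matrix.mean(axis=0),
        n_trials=matrix.shape[0],
        fs=sig.fs,
        excluded_trials=tuple(excluded),
    )


def response_metrics(
    peth: TrialPETH,
    response_win: float = 1.0,
    baseline_win: float = 2.0,
) -> ResponseMetrics:
    """Peak, latency, half-maximum width and AUC of the mean response.

    The peak is the maximum of the trial-mean trace within
    ``(0, response_win]``; half-maximum crossings are searched outward
    from the peak (half-max level = peak/2, the baseline being zero by
    construction after z-scoring); the window edge substitutes for a
    crossing that never occurs.  AUC sums the mean-trace samples
    between the crossings divided by the sampling rate.
    """
    peth.window_slice(-baseline_win, 0.0)  # coverage check
    resp_idx = peth.window_slice(0.0, response_win)
    trace = peth.mean
    peak_pos = resp_idx[np.argmax(trace[resp_idx])]
    peak = float(trace[peak_pos])
    latency = float(peth.bin_centers[peak_pos])
    flag = "" if peak > 0 else "no positive response"

    level = peak / 2.0
    lo = peak_pos
    while lo > resp_idx[0] and trace[lo - 1] >= level:
        lo -= 1
    hi = peak_pos
    while hi < resp_idx[-1] and trace[hi + 1] >= level:
        hi += 1
    if peak <= 0:  # degenerate: no crossings definable
        lo, hi = resp_idx[0], resp_idx[-1]
    duration = float(peth.bin_centers[hi] - peth.bin_centers[lo] + 1.0 / peth.fs)
    auc = float(trace[lo : hi + 1].sum() / peth.fs)
    return ResponseMetrics(peak=peak, latency=latency, duration=duration, auc=auc, flag=flag)


def trialwise_cue_test(
    peth: TrialPETH,
    resp_win: tuple[float, float] = (0.0, 0.5),
    base_win: tuple[float, float] = (-0.5, 0.0),
    alpha: float = 0.05,
) -> dict:
    """Paired trialwise test of cue responses against baseline fluctuations.

    Per trial, the maximum over the response window is paired with the
    maximum over the pre-stimulus baseline window; a one-sided Wilcoxon
    signed-rank test asks whether responses exceed baseline.  Latency
    and duration are meaningful only for significant sessions, mirrored
    by the returned ``significant`` gate.
    """
    if peth.n_trials < 10:
        raise ValidationError("need at least 10 trials")
    x = peth.matrix[:, peth.window_slice(*resp_win)].max(axis=1)
    y = peth.matrix[:, peth.window_slice(*base_win)].max(axis=1)
    d = x - y
    if np.all(d == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(x, y, alternative="greater").pvalue)
    return {"significant": p < alpha, "p": p, "n_trials": peth.n_trials}
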