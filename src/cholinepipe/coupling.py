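"""Cross-signal analyses: normalized cross-correlation with common-mode
rejection, pupil-diameter geometry, calcium-peak-triggered averaging,
and transfer entropy on discretized series.

The cross-correlogram (CCR) between two signals is normalized by the
geometric mean of the zero-lag autocorrelations,
``R_norm(t) = R_xy(t) / sqrt(R_xx(0) R_yy(0))``, so it lies in [-1, 1];
a central ±20 ms window is excluded before peak finding to reject
common-mode noise, and curves are restricted to ±10 s.

Transfer entropy TE(x -> y) quantifies how much the past of x reduces
uncertainty about the present of y beyond y's own past.  Series are
z-scored, downsampled by block averaging, discretized into equal-width
bins, and TE computed with plug-in probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import CalciumSignal, PupilLandmarks, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CrossCorrelogram",
    "TransferEntropyResult",
    "normalized_xcorr",
    "average_ccr",
    "pupil_diameter",
    "peak_triggered_average",
    "transfer_entropy",
]


@dataclass(frozen=True)
class CrossCorrelogram:
    lags: np.ndarray          # s, symmetric around 0
    values: np.ndarray        # normalized correlation
    excluded_mask: np.ndarray  # True where masked as common-mode
    peak_value: float
    peak_lag: float
    fs: float


@dataclass(frozen=True)
class TransferEntropyResult:
    te_xy: float
    te_yx: float
    n_bins: int
    history_len: int
    n_samples: int
    base: float = 2.0  # 2 -> bits


def normalized_xcorr(
    x: CalciumSignal,
    y: CalciumSignal,
    max_lag: float = 10.0,
    exclude: float = 0.020,
    center: bool = True,
) -> CrossCorrelogram:
    """Normalized cross-correlogram of two same-rate signals.

    Positive lag means the second signal lags the first (x leads).
    Values are the raw lagged dot products of the (optionally
    mean-centered) signals divided by ``sqrt(R_xx(0) R_yy(0))``; lags
    within ``±exclude`` are masked before the peak search.
    """
    if abs(x.fs - y.fs) > 1e-9:
        raise ValidationError("signals must share a sampling rate")
    if len(x.dff) != len(y.dff):
        raise ValidationError("signals must have equal length")
    fs = x.fs
    n = len(x.dff)
    if n < 2 * max_lag * fs:
        raise ValidationError("signals too short for the requested max_lag")
    xv = x.dff - x.dff.mean() if center else x.dff.astype(float)
    yv = y.dff - y.dff.mean() if center else y.dff.astype(float)
    rxx0 = float(np.dot(xv, xv))
    ryy0 = float(np.dot(yv, yv))
    if rxx0 == 0 or ryy0 == 0:
        raise ValidationError("zero-variance signal")

    # full[k] = sum_t y[t] x[t - (k - (n-1))]; positive lag -> y lags x
    full = sps.correlate(yv, xv, mode="full", method="fft")
    lags_full = np.arange(-(n - 1), n) / fs
    keep = np.abs(lags_full) <= max_lag + 1e-12
    lags = lags_full[keep]
    values = full[keep] / np.sqrt(rxx0 * ryy0)
    mask = np.abs(lags) <= exclude + 1e-12

    avail = ~mask
    peak_pos = np.flatnonzero(avail)[np.argmax(values[avail])]
    return CrossCorrelogram(
        lags=lags,
        values=values,
        excluded_mask=mask,
        peak_value=float(values[peak_pos]),
        peak_lag=float(lags[peak_pos]),
        fs=fs,
    )


def average_ccr(sessions: list[CrossCorrelogram]) -> tuple[CrossCorrelogram, list[dict]]:
    """Average CCR curves across sessions; tabulate per-session peaks.

    All sessions must share the lag grid.  The average honors the
    exclusion masks (masked bins stay masked).  The per-session table
    records each session's maximal CCR and its lag, the per-animal
    summary statistic of the study design.
    """
    first = sessions[0]
    for s in sessions[1:]:
        if len(s.lags) != len(first.lags) or np.any(np.abs(s.lags - first.lags) > 1e-12):
            raise ValidationError("inconsistent lag grids")
    stacked = np.vstack([s.values for s in sessions])
    mean_vals = stacked.mean(axis=0)
    mask = first.excluded_mask
    avail = ~mask
    peak_pos = np.flatnonzero(avail)[np.argmax(mean_vals[avail])]
    avg = CrossCorrelogram(
        lags=first.lags,
        values=mean_vals,
        excluded_mask=mask,
        peak_value=float(mean_vals[peak_pos]),
        peak_lag=float(first.lags[peak_pos]),
        fs=first.fs,
    )
    table = [
        {"session": i, "peak_value": s.peak_value, "peak_lag": s.peak_lag}
        for i, s in enumerate(sessions)
    ]
    return avg, table


def pupil_diameter(
    landmarks: PupilLandmarks,
    target_t: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pupil diameter as the mean distance of the three diagonal pairs.

    Frames with any missing (NaN) landmark are dropped and linearly
    interpolated over.  If ``target_t`` is given (e.g. the photometry
    time grid), the diameter is interpolated onto it; returns
    ``(t, diameter)`` in pixels.
    """
    d = np.linalg.norm(
        landmarks.pairs[:, :, 0, :] - landmarks.pairs[:, :, 1, :], axis=2
    )  # frames x 3
    diam = d.mean(axis=1)
    good = np.isfinite(diam)
    n_bad = int((~good).sum())
    if n_bad:
        logger.info("dropped and interpolated %d frame(s) with missing landmarks", n_bad)
    if not good.any():
        raise ValidationError("no frames with complete landmarks")
    t_good, d_good = landmarks.t[good], diam[good]
    if target_t is None:
        return landmarks.t, np.interp(landmarks.t, t_good, d_good)
    target_t = np.asarray(target_t, dtype=float)
    return target_t, np.interp(target_t, t_good, d_good)


def peak_triggered_average(
    sig: CalciumSignal,
    target: np.ndarray,
    threshold_sd: float = 2.0,
    min_separation: float = 1.0,
    window: tuple[float, float] = (-2.0, 4.0),
) -> dict:
    """Average a target series around detected calcium transient peaks.

    Peaks are local maxima of the z-scored signal exceeding
    ``threshold_sd`` with at least ``min_separation`` seconds between
    them; the target (e.g. pupil diameter on the same grid) is averaged
    in ``window`` around each usable peak.
    """
    target = np.asarray(target, dtype=float)
    if len(target) != len(sig.dff):
        raise ValidationError("target must share the signal's grid")
    z = (sig.dff - sig.dff.mean()) / sig.dff.std()
    peaks, _ = sps.find_peaks(
        z, height=threshold_sd, distance=max(1, int(round(min_separation * sig.fs)))
    )
    n_pre = int(round(-window[0] * sig.fs))
    n_post = int(round(window[1] * sig.fs))
    peaks = peaks[(peaks >= n_pre) & (peaks + n_post <= len(target))]
    if peaks.size == 0:
        raise ValidationError(
            "no transient peaks detected; lower threshold_sd or check the signal"
        )
    segments = np.vstack([target[p - n_pre : p + n_post] for p in peaks])
    rel = np.arange(-n_pre, n_post) / sig.fs
    return {
        "lags": rel,
        "average": segments.mean(axis=0),
        "n_peaks": int(peaks.size),
        "peak_times": sig.t[peaks],
    }


def _block_downsample(x: np.ndarray, factor: int) -> np.ndarray:
    n = (len(x) // factor) * factor
    return x[:n].reshape(-1, factor).mean(axis=1)


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each point to one of ``n_bins`` equal-width bins over [min, max]."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValidationError("zero entropy source: constant series")
    idx = np.floor((x - lo) / (hi - lo) * n_bins).astype(np.int64)
    return np.minimum(idx, n_bins - 1)


def _te_directed(src: np.ndarray, dst: np.ndarray, h: int, base: float) -> float:
    """Plug-in transfer entropy src -> dst with history length ``h``."""
    n = len(dst)
    # encode h-sample histories as single integers
    k = int(max(src.max(), dst.max())) + 1
    dst_past = np.zeros(n - h, dtype=np.int64)
    src_past = np.zeros(n - h, dtype=np.int64)
    for j in range(h):
        dst_past = dst_past * k + dst[j : n - h + j]
        src_past = src_past * k + src[j : n - h + j]
    dst_now = dst[h:]

    # joint counts via a dictionary over (now, dst_past, src_past)
    triple = np.stack([dst_now, dst_past, src_past])
    _, inv3, c3 = np.unique(triple, axis=1, return_inverse=True, return_counts=True)
    _, inv2a, c2a = np.unique(
        np.stack([dst_now, dst_past]), axis=1, return_inverse=True, return_counts=True
    )
    _, inv2b, c2b = np.unique(
        np.stack([dst_past, src_past]), axis=1, return_inverse=True, return_counts=True
    )
    _, inv1, c1 = np.unique(dst_past, return_inverse=True, return_counts=True)

    n_eff = len(dst_now)
    # TE = (1/n) sum over samples log[ p(yt|yp,xp) / p(yt|yp) ]
    #    = mean log[ (c3/c2b) / (c2a/c1) ] evaluated at each sample's cells
    ratio = (c3[inv3] / c2b[inv2b]) / (c2a[inv2a] / c1[inv1])
    te = float(np.mean(np.log(ratio) / np.log(base)))
    return max(te, 0.0)


def transfer_entropy(
    x: np.ndarray,
    y: np.ndarray,
    n_bins: int = 200,
    history_len: int = 1,
    fs: float | None = None,
    downsample_to: float | None = None,
    base: float = 2.0,
) -> TransferEntropyResult:
    """Transfer entropy in both directions between two series.

    Each series is z-scored, optionally block-averaged from ``fs`` down
    to ``downsample_to`` Hz, and discretized into ``n_bins`` equal-width
    bins spanning its own [min, max].  TE uses plug-in probabilities
    over (present, own past, other past) with ``history_len`` samples
    of history; ``base=2`` reports bits.

    Plug-in TE is positively biased at small n / large ``n_bins``; for
    the default 200 bins treat absolute values as descriptive and
    compare directions rather than magnitudes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("series must have equal length")
    if downsample_to is not None:
        if fs is None:
            raise ValidationError("fs required for downsampling")
        factor = int(round(fs / downsample_to))
        if factor > 1:
            x = _block_downsample(x, factor)
            y = _block_downsample(y, factor)
    if len(x) < 100 * history_len:
        raise ValidationError("series too short for the requested history length")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero entropy source: constant series")
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    xd = _discretize(xz, n_bins)
    yd = _discretize(yz, n_bins)
    te_xy = _te_directed(xd, yd, history_len, base)
    te_yx = _te_directed(yd, xd, history_len, base)
    return TransferEntropyResult(
        te_xy=te_xy,
        te_yx=te_yx,
        n_bins=n_bins,
        history_len=history_len,
        n_samples=len(xd),
        base=base,
    )
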