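"""Peri-event spike analyses: PETHs, event-response detection,
optotagging, and response-based cell typing.

The response-detection procedure mirrors the event-related firing-rate
analysis of the study design: PETH extremum within 500 ms of the event,
baseline from the preceding 500 ms, a response window bounded by the
half-distance crossings around the extremum, a matched window around
the corresponding local extremum of the baseline period, and a
one-sided Mann-Whitney U test on per-trial spike counts at p < 0.01.
When activation and inhibition are both significant, the earlier window
is the primary response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA

from .types import EventSeries, SpikeTrain, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PETH",
    "ResponseCall",
    "CellTypeCall",
    "compute_peth",
    "detect_event_response",
    "optotag",
    "cluster_cell_types",
]


@dataclass(frozen=True)
class PETH:
    """Peri-event time histogram with per-trial spike counts."""

    bin_centers: np.ndarray
    rate: np.ndarray
    per_trial_counts: np.ndarray
    n_trials: int
    trigger_label: str
    bin_width: float

    def window_slice(self, lo: float, hi: float) -> np.ndarray:
        """Indices of bins fully inside the half-open window [lo, hi)."""
        starts = self.bin_centers - self.bin_width / 2
        idx = np.flatnonzero((starts >= lo - 1e-12) & (starts + self.bin_width <= hi + 1e-12))
        if idx.size == 0:
            raise ValidationError(f"PETH does not cover window [{lo}, {hi})")
        return idx


@dataclass(frozen=True)
class ResponseCall:
    direction: str  # activation | inhibition | none
    primary: str
    peak_or_trough_rate: float
    baseline_rate: float
    window: tuple[float, float]
    p_value: float
    p_activation: float = 1.0
    p_inhibition: float = 1.0


@dataclass(frozen=True)
class CellTypeCall:
    unit_index: int
    pc_scores: np.ndarray
    cluster: int
    putative_class: str


def compute_peth(
    train: SpikeTrain,
    events: EventSeries,
    window: tuple[float, float] = (-0.5, 0.5),
    bin_width: float = 0.010,
) -> PETH:
    """Bin spikes around each event into a trials x bins count matrix.

    Events whose window extends beyond the recording span are dropped
    (logged).  Bins are half-open; ``rate`` is the trial-mean count per
    bin divided by the bin width.
    """
    pre, post = window
    if post <= pre:
        raise ValidationError("window end must exceed start")
    n_bins = int(round((post - pre) / bin_width))
    if abs(n_bins * bin_width - (post - pre)) > 1e-9:
        raise ValidationError("bin_width must divide the window length")
    usable = events.times[
        (events.times + pre >= train.t_start) & (events.times + post <= train.t_end)
    ]
    n_dropped = events.n_events - usable.size
    if n_dropped:
        logger.info(
            "%s/%s: dropped %d event(s) too close to recording edges",
            train.unit_id,
            events.label,
            n_dropped,
        )
    if usable.size == 0:
        raise ValidationError("no usable events within the recording span")
    edges = pre + np.arange(n_bins + 1) * bin_width
    counts = np.empty((usable.size, n_bins), dtype=np.int64)
    for i, ev in enumerate(usable):
        rel = train.times[np.searchsorted(train.times, ev + pre) : np.searchsorted(train.times, ev + post)] - ev
        # half-open bins [edge_k, edge_{k+1})
        counts[i] = np.histogram(rel, bins=edges)[0]
        at_end = np.isclose(rel, post).sum()  # np.histogram closes the last bin
        if at_end:
            counts[i, -1] -= at_end
    centers = edges[:-1] + bin_width / 2
    rate = counts.mean(axis=0) / bin_width
    return PETH(
        bin_centers=centers,
        rate=rate,
        per_trial_counts=counts,
        n_trials=usable.size,
        trigger_label=events.label,
        bin_width=bin_width,
    )


def _mannwhitney_one_sided(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """One-sided Mann-Whitney U p-value; 1.0 on fully tied degenerate data.

    Uses the normal approximation with tie correction throughout: spike
    counts are heavily tied integers, for which no exact null
    distribution is available.
    """
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    return float(
        stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic").pvalue
    )


def _direction_call(
    peth: PETH,
    direction: str,
    search_win: float,
    baseline_win: float,
    smooth_sd: float | None,
) -> tuple[float, tuple[float, float], float, float]:
    """One direction of the response procedure.

    Returns (extremum rate, response window, baseline rate, p-value).
    Window finding optionally uses a Gaussian-smoothed PETH (``smooth_sd``
    seconds) so single noisy bins do not truncate the half-distance
    walk; the Mann-Whitney test always uses raw per-trial counts.
    """
    sign = 1.0 if direction == "activation" else -1.0
    resp_idx = peth.window_slice(0.0, search_win)
    base_idx = peth.window_slice(-baseline_win, 0.0)
    baseline = float(peth.rate[base_idx].mean())

    if smooth_sd:
        rate = gaussian_filter1d(peth.rate, smooth_sd / peth.bin_width)
    else:
        rate = peth.rate
    signed = sign * rate
    ext_pos = resp_idx[np.argmax(signed[resp_idx])]
    extremum = float(rate[ext_pos])
    if sign * (extremum - baseline) <= 0:
        return extremum, (0.0, 0.0), baseline, 1.0

    # Half-distance crossings before and after the extremum, within the
    # search window; if the rate never recrosses, the window is bounded
    # by the search-window edge.
    level = baseline + 0.5 * (extremum - baseline)
    lo = ext_pos
    while lo > resp_idx[0] and signed[lo - 1] >= sign * level:
        lo -= 1
    hi = ext_pos
    while hi < resp_idx[-1] and signed[hi + 1] >= sign * level:
        hi += 1
    win_start = float(peth.bin_centers[lo] - peth.bin_width / 2)
    win_end = float(peth.bin_centers[hi] + peth.bin_width / 2)

    # Matched window of identical length centered on the same-signed
    # local extremum of the baseline period; at the baseline-span edges
    # the window shifts inward rather than truncating, so the two count
    # samples always cover the same number of bins and the
    # extremum-selection effect cancels between them.
    n_win = hi - lo + 1
    base_ext = base_idx[np.argmax(signed[base_idx])]
    half = (n_win - 1) // 2
    b_lo = base_ext - half
    b_hi = b_lo + n_win - 1
    if b_lo < base_idx[0]:
        b_lo, b_hi = base_idx[0], base_idx[0] + n_win - 1
    if b_hi > base_idx[-1]:
        b_lo, b_hi = base_idx[-1] - n_win + 1, base_idx[-1]
    b_lo = max(b_lo, base_idx[0])

    x = peth.per_trial_counts[:, lo : hi + 1].sum(axis=1)
    y = peth.per_trial_counts[:, b_lo : b_hi + 1].sum(axis=1)
    alternative = "greater" if direction == "activation" else "less"
    p = _mannwhitney_one_sided(x, y, alternative)
    return extremum, (win_start, win_end), baseline, p


def detect_event_response(
    peth: PETH,
    search_win: float = 0.5,
    baseline_win: float = 0.5,
    alpha: float = 0.01,
    smooth_sd: float | None = 0.020,
) -> ResponseCall:
    """Detect significant event-locked activation and/or inhibition.

    Both directions are tested; a flat PETH returns direction "none"
    with p = 1.  If both reach significance the direction whose
    response window starts earlier is designated primary.
    ``smooth_sd`` (s) smooths the PETH for extremum/window finding
    only; the significance test always uses raw per-trial counts.
    """
    ext_a, win_a, base, p_a = _direction_call(peth, "activation", search_win, baseline_win, smooth_sd)
    ext_i, win_i, _, p_i = _direction_call(peth, "inhibition", search_win, baseline_win, smooth_sd)

    sig_a = p_a < alpha
    sig_i = p_i < alpha
    if sig_a and sig_i:
        primary = "activation" if win_a[0] <= win_i[0] else "inhibition"
    elif sig_a:
        primary = "activation"
    elif sig_i:
        primary = "inhibition"
    else:
        primary = "none"

    if primary == "inhibition":
        direction, ext, win, p = "inhibition", ext_i, win_i, p_i
    elif primary == "activation":
        direction, ext, win, p = "activation", ext_a, win_a, p_a
    else:
        direction, ext, win, p = "none", ext_a, (0.0, 0.0), min(p_a, p_i)
    return ResponseCall(
        direction=direction,
        primary=primary,
        peak_or_trough_rate=ext,
        baseline_rate=base,
        window=win,
        p_value=p,
        p_activation=p_a,
        p_inhibition=p_i,
    )


def optotag(
    train: SpikeTrain,
    laser: EventSeries,
    pulse_dur: float = 0.2,
    latency_max: float = 0.010,
    max_rate: float = 0.5,
    baseline_win: float = 1.0,
    bin_width: float = 0.001,
) -> dict:
    """Classify a unit as opsin-tagged by rapid light-evoked suppression.

    Tagged iff (a) the mean rate during the pulses (from ``latency_max``
    to pulse offset) stays at or below ``max_rate`` and (b) the
    pulse-aligned PETH (1 ms bins, 5-point smoothed) falls below half
    the pre-pulse baseline rate within ``latency_max`` of pulse onset.
    """
    if laser.n_events < 10:
        raise ValidationError("need at least 10 laser pulses")
    peth = compute_peth(train, laser, window=(-baseline_win, pulse_dur), bin_width=bin_width)
    base_idx = peth.window_slice(-baseline_win, 0.0)
    baseline_rate = float(peth.rate[base_idx].mean())
    if baseline_rate == 0:
        return {
            "tagged": False,
            "flag": "silent unit",
            "baseline_rate": 0.0,
            "pulse_rate": 0.0,
            "latency": np.nan,
        }
    pulse_idx = peth.window_slice(latency_max, pulse_dur)
    pulse_rate = float(peth.rate[pulse_idx].mean())

    kernel = np.ones(5) / 5
    smoothed = np.convolve(peth.rate, kernel, mode="same")
    post_idx = peth.window_slice(0.0, pulse_dur)
    below = post_idx[smoothed[post_idx] < 0.5 * baseline_rate]
    latency = float(peth.bin_centers[below[0]] - bin_width / 2) if below.size else np.inf

    tagged = (pulse_rate <= max_rate) and (latency < latency_max)
    return {
        "tagged": bool(tagged),
        "flag": "",
        "baseline_rate": baseline_rate,
        "pulse_rate": pulse_rate,
        "latency": latency,
    }


def cluster_cell_types(
    responses: np.ndarray,
    n_clusters: int = 4,
    n_components: int = 3,
    linkage: str = "ward",
    reward_cols: slice | None = None,
    punish_cols: slice | None = None,
) -> list[CellTypeCall]:
    """PCA + hierarchical clustering of reward/punishment response profiles.

    ``responses`` is a units x features matrix of z-scored PETHs, the
    reward-aligned block followed by the punishment-aligned block
    (``reward_cols`` / ``punish_cols`` override the equal split).  The
    first ``n_components`` principal-component scores are clustered by
    agglomerative (Ward, Euclidean) linkage into ``n_clusters`` groups.
    The cluster whose mean response is positive after both rewards and
    punishments is labeled putative-cholinergic; mixed-sign clusters
    glutamatergic-like; both-negative clusters GABAergic-like.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.shape[0] < n_clusters:
        raise ValidationError("need at least as many units as clusters")
    if not np.all(np.isfinite(responses)):
        raise ValidationError("response matrix contains nonfinite values")
    if np.linalg.matrix_rank(responses - responses.mean(axis=0)) < n_components:
        raise ValidationError(
            "response matrix rank below requested components; provide more units or bins"
        )
    half = responses.shape[1] // 2
    reward_cols = reward_cols or slice(0, half)
    punish_cols = punish_cols or slice(half, responses.shape[1])

    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(responses)
    labels = AgglomerativeClustering(n_clusters=n_clusters, linkage=linkage).fit_predict(scores)

    class_of: dict[int, str] = {}
    chol_candidates = []
    for c in range(n_clusters):
        members = responses[labels == c]
        r_mean = members[:, reward_cols].mean()
        p_mean = members[:, punish_cols].mean()
        if r_mean > 0 and p_mean > 0:
            chol_candidates.append((r_mean + p_mean, c))
            class_of[c] = "putative-cholinergic"
        elif r_mean <= 0 and p_mean <= 0:
            class_of[c] = "GABAergic-like"
        else:
            class_of[c] = "glutamatergic-like"
    if len(chol_candidates) > 1:
        # keep only the strongest both-activated cluster as cholinergic
        chol_candidates.sort(reverse=True)
        for _, c in chol_candidates[1:]:
            class_of[c] = "glutamatergic-like"

    return [
        CellTypeCall(
            unit_index=i,
            pc_scores=scores[i],
            cluster=int(labels[i]) + 1,
            putative_class=class_of[int(labels[i])],
        )
        for i in range(responses.shape[0])
    ]
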