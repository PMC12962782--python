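"""Core domain containers shared across the pipeline.

All timestamps and windows are in seconds; conversion to ms happens only
when formatting output tables.  Time intervals are half-open ``[a, b)``
throughout, so adjacent bins tile without double counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "EventSeries",
    "TrialTable",
    "PhotometrySession",
    "CalciumSignal",
    "PupilLandmarks",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike timestamps of one unit.

    Parameters
    ----------
    unit_id : str
        Label of the unit.
    times : ndarray
        Strictly increasing spike times in seconds.
    t_start, t_end : float
        Recording span; every spike must fall inside ``[t_start, t_end]``.
    """

    unit_id: str
    times: np.ndarray
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.t_end <= self.t_start:
            raise ValidationError(
                f"t_end ({self.t_end}) must exceed t_start ({self.t_start})"
            )
        if times.size:
            if not np.all(np.isfinite(times)):
                raise ValidationError(f"unit {self.unit_id}: nonfinite spike time")
            if np.any(np.diff(times) <= 0):
                raise ValidationError(
                    f"unit {self.unit_id}: spike times not strictly increasing"
                )
            if times[0] < self.t_start or times[-1] > self.t_end:
                raise ValidationError(
                    f"unit {self.unit_id}: spike outside [{self.t_start}, {self.t_end}]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def rate(self) -> float:
        """Mean firing rate over the recording span (Hz)."""
        return self.n_spikes / self.duration


@dataclass(frozen=True)
class EventSeries:
    """Timestamps of one event type (cue, reward, laser pulse, lick...)."""

    label: str
    times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size and np.any(np.diff(times) < 0):
            raise ValidationError(f"events '{self.label}': times decrease")

    @property
    def n_events(self) -> int:
        return int(self.times.size)


VALID_OUTCOMES = ("reward", "punishment", "omission")


@dataclass(frozen=True)
class TrialTable:
    """Per-trial cue and outcome timing of the conditioning task.

    Stored as a DataFrame with columns ``cue_time`` (s), ``cue_id`` (1|2),
    ``outcome_time`` (s, NaN on omission trials) and ``outcome``
    (reward|punishment|omission).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cue_time", "cue_id", "outcome_time", "outcome"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(f"trial table missing columns: {sorted(missing)}")
        df = self.df.reset_index(drop=True)
        object.__setattr__(self, "df", df)
        if np.any(np.diff(df["cue_time"].to_numpy(float)) <= 0):
            raise ValidationError("cue_time must be strictly increasing")
        bad = ~df["outcome"].isin(VALID_OUTCOMES)
        if bad.any():
            raise ValidationError(
                f"unknown outcome values: {sorted(df.loc[bad, 'outcome'].unique())}"
            )
        omission = df["outcome"] == "omission"
        if df.loc[omission, "outcome_time"].notna().any():
            raise ValidationError("omission trial has an outcome_time")
        delivered = df.loc[~omission]
        if delivered["outcome_time"].isna().any():
            raise ValidationError("delivered outcome missing outcome_time")
        if (delivered["outcome_time"] <= delivered["cue_time"]).any():
            raise ValidationError("outcome_time must follow cue_time")

    @property
    def n_trials(self) -> int:
        return len(self.df)

    def events(self, label: str) -> EventSeries:
        """Extract an :class:`EventSeries` (cue1, cue2, reward, punishment)."""
        df = self.df
        if label in ("cue1", "cue2"):
            cue_id = int(label[-1])
            times = df.loc[df["cue_id"] == cue_id, "cue_time"]
        elif label in ("reward", "punishment"):
            times = df.loc[df["outcome"] == label, "outcome_time"]
        elif label == "cue":
            times = df["cue_time"]
        else:
            raise KeyError(f"unknown event label {label!r}")
        return EventSeries(label, np.sort(times.to_numpy(float)))


@dataclass(frozen=True)
class PhotometrySession:
    """Two-channel fiber-photometry recording on a uniform time grid.

    ``f465`` is the calcium-dependent channel, ``f405`` the isosbestic
    (calcium-independent) control carrying motion artifact and
    autofluorescence.
    """

    t: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        f465 = np.asarray(self.f465, dtype=float)
        f405 = np.asarray(self.f405, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "f465", f465)
        object.__setattr__(self, "f405", f405)
        if t.size < 2:
            raise ValidationError("photometry session needs >= 2 samples")
        if len(f465) != len(t) or len(f405) != len(t):
            raise ValidationError("channel length does not match time grid")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        dt = np.diff(t)
        if np.any(np.abs(dt - 1.0 / self.fs) > 1e-9 * max(1.0, abs(t[-1]))):
            raise ValidationError("time grid is not uniform at fs")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class CalciumSignal:
    """A preprocessed dF/F trace (percent) with its provenance."""

    t: np.ndarray
    dff: np.ndarray
    fs: float
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        dff = np.asarray(self.dff, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "dff", dff)
        if len(dff) != len(t):
            raise ValidationError("dff length does not match time grid")
        if not np.all(np.isfinite(dff)):
            raise ValidationError("dff contains nonfinite values")


@dataclass(frozen=True)
class PupilLandmarks:
    """Tracked pupil-edge and eyelid landmark coordinates per video frame.

    ``pairs`` has shape (n_frames, 3, 2, 2): three diagonal point pairs,
    each pair two planar points (x, y) in pixels.  ``eyelid`` has shape
    (n_frames, 2, 2).  Frames with missing landmarks carry NaN.
    """

    t: np.ndarray
    pairs: np.ndarray
    eyelid: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        pairs = np.asarray(self.pairs, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "pairs", pairs)
        if pairs.shape != (t.size, 3, 2, 2):
            raise ValidationError(
                f"pairs must have shape (n_frames, 3, 2, 2), got {pairs.shape}"
            )
        if t.size and np.any(np.diff(t) < 0):
            raise ValidationError("frame times decrease")
        if self.eyelid is not None:
            eyelid = np.asarray(self.eyelid, dtype=float)
            object.__setattr__(self, "eyelid", eyelid)
            if eyelid.shape != (t.size, 2, 2):
                raise ValidationError("eyelid must have shape (n_frames, 2, 2)")
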