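"""Readers and writers for the pipeline's tabular file formats.

All files are plain CSV/TSV: comma-separated, header row, UTF-8,
``.`` decimal — the dialect of typical photometry-system exports.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    EventSeries,
    PhotometrySession,
    PupilLandmarks,
    SpikeTrain,
    TrialTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_spike_trains",
    "write_spike_trains",
    "read_photometry",
    "write_photometry",
    "read_trials",
    "write_trials",
    "validate_trials",
    "read_pupil_landmarks",
    "write_pupil_landmarks",
]


def read_spike_trains(path: str | Path, t_start: float, t_end: float) -> list[SpikeTrain]:
    """Read spike trains from a CSV file.

    Two layouts are accepted: a single ``time`` column (one unit, named
    after the file stem) or a long format with ``unit_id`` and ``time``
    columns.  Unsorted times are sorted with a logged warning; times
    outside ``[t_start, t_end]`` raise :class:`ValidationError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return [SpikeTrain(path.stem, np.empty(0), t_start, t_end)]
    if df.empty:
        return [SpikeTrain(path.stem, np.empty(0), t_start, t_end)]
    if "unit_id" in df.columns:
        groups = [(str(uid), sub["time"]) for uid, sub in df.groupby("unit_id", sort=True)]
    else:
        col = "time" if "time" in df.columns else df.columns[0]
        groups = [(path.stem, df[col])]

    trains = []
    for unit_id, series in groups:
        times = pd.to_numeric(series, errors="coerce").to_numpy(float)
        if np.any(np.isnan(times)):
            line = int(series.index[np.isnan(times)][0]) + 2  # +header +0-base
            raise ValidationError(f"{path}: nonnumeric timestamp at line {line}")
        if np.any((times < t_start) | (times > t_end)):
            raise ValidationError(
                f"{path}: unit {unit_id} has times outside [{t_start}, {t_end}]"
            )
        if np.any(np.diff(times) < 0):
            logger.warning("%s: unit %s unsorted; sorting", path, unit_id)
            times = np.sort(times)
        times = np.unique(times)  # strictly increasing
        trains.append(SpikeTrain(unit_id, times, t_start, t_end))
    return trains


def write_spike_trains(trains: list[SpikeTrain], path: str | Path) -> None:
    """Write trains in long format (unit_id, time)."""
    rows = [
        {"unit_id": tr.unit_id, "time": t} for tr in trains for t in tr.times
    ]
    pd.DataFrame(rows, columns=["unit_id", "time"]).to_csv(path, index=False)


def read_photometry(
    path: str | Path,
    time_column: str = "time",
    f465_column: str = "f465",
    f405_column: str = "f405",
) -> PhotometrySession:
    """Read a two-channel photometry CSV.

    Sampling rate is inferred from the median time step; a nonuniform
    grid (dropped samples) is linearly resampled onto a uniform grid
    with a logged note.
    """
    df = pd.read_csv(path)
    for col in (time_column, f465_column, f405_column):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    t = df[time_column].to_numpy(float)
    if t.size < 2:
        raise ValidationError(f"{path}: need at least 2 samples")
    f465 = df[f465_column].to_numpy(float)
    f405 = df[f405_column].to_numpy(float)
    dt = np.median(np.diff(t))
    fs = 1.0 / dt
    uniform = np.all(np.abs(np.diff(t) - dt) <= 1e-9 * max(1.0, abs(t[-1])))
    if not uniform:
        n = int(round((t[-1] - t[0]) / dt)) + 1
        tu = t[0] + np.arange(n) * dt
        logger.info("%s: nonuniform grid; resampled %d -> %d samples", path, t.size, n)
        f465 = np.interp(tu, t, f465)
        f405 = np.interp(tu, t, f405)
        t = tu
    return PhotometrySession(t=t, f465=f465, f405=f405, fs=fs)


def write_photometry(session: PhotometrySession, path: str | Path) -> None:
    pd.DataFrame(
        {"time": session.t, "f465": session.f465, "f405": session.f405}
    ).to_csv(path, index=False)


def read_trials(path: str | Path) -> TrialTable:
    """Read a trial table (TSV or CSV by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    return TrialTable(df)


def write_trials(trials: TrialTable, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    trials.df.to_csv(path, sep=sep, index=False)


def validate_trials(trials: TrialTable, min_iti: float = 2.5) -> pd.DataFrame:
    """Sanity-check inter-cue intervals against the task's minimum ITI.

    Returns the trial table with a boolean ``iti_ok`` column; trials
    whose cue follows the previous one by less than ``min_iti`` are
    flagged False.  (Type invariants — e.g. no outcome_time on omission
    trials — are enforced by :class:`TrialTable` itself.)
    """
    df = trials.df.copy()
    iti = np.diff(df["cue_time"].to_numpy(float), prepend=-np.inf)
    df["iti_ok"] = iti >= min_iti
    df.loc[df.index[0], "iti_ok"] = True
    n_bad = int((~df["iti_ok"]).sum())
    if n_bad:
        logger.warning("%d trial(s) violate min ITI %.3g s", n_bad, min_iti)
    return df


_PAIR_COLS = [
    f"{p}{i}_{axis}" for i in (1, 2, 3) for p in ("p", "q") for axis in ("x", "y")
]
_LID_COLS = [f"l{i}_{axis}" for i in (1, 2) for axis in ("x", "y")]


def read_pupil_landmarks(path: str | Path) -> PupilLandmarks:
    """Read pupil landmark coordinates.

    Columns: ``time``, then for each diagonal pair i in 1..3 the points
    ``pi_x, pi_y, qi_x, qi_y``, optionally eyelid ``l1_x..l2_y``.
    """
    df = pd.read_csv(path)
    t = df["time"].to_numpy(float)
    n = t.size
    pairs = np.full((n, 3, 2, 2), np.nan)
    for i in range(3):
        for j, p in enumerate(("p", "q")):
            for k, axis in enumerate(("x", "y")):
                pairs[:, i, j, k] = df[f"{p}{i + 1}_{axis}"].to_numpy(float)
    eyelid = None
    if _LID_COLS[0] in df.columns:
        eyelid = np.stack(
            [
                np.column_stack([df[f"l{i}_x"], df[f"l{i}_y"]])
                for i in (1, 2)
            ],
            axis=1,
        ).astype(float)
    return PupilLandmarks(t=t, pairs=pairs, eyelid=eyelid)


def write_pupil_landmarks(lm: PupilLandmarks, path: str | Path) -> None:
    data = {"time": lm.t}
    for i in range(3):
        for j, p in enumerate(("p", "q")):
            for k, axis in enumerate(("x", "y")):
                data[f"{p}{i + 1}_{axis}"] = lm.pairs[:, i, j, k]
    if lm.eyelid is not None:
        for i in range(2):
            for k, axis in enumerate(("x", "y")):
                data[f"l{i + 1}_{axis}"] = lm.eyelid[:, i, k]
    pd.DataFrame(data).to_csv(path, index=False)
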