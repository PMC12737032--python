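"""Raw/activity CSV input-output, timestamp regularization, and a
sphere-fit auto-calibration substitute.

CSV dialects (comma-separated, dot decimal, header required):

* raw acceleration: ``timestamp_ms,x,y,z``
* epoch activity:   ``epoch_start_ms,value,method``
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import (ActivitySeries, CalibrationReport, FormatError,
                   TriaxialRecording)

RAW_COLUMNS = ("timestamp_ms", "x", "y", "z")
ACTIVITY_COLUMNS = ("epoch_start_ms", "value", "method")


@dataclass
class GapReport:
    """Summary of grid slots that had no input sample."""

    n_gap_events: int = 0   # maximal runs of empty slots
    n_filled: int = 0       # total slots filled by repeating the last sample


def _read_table(path, columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    numeric = [c for c in columns if c != "method"]
    for c in numeric:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna() | df[c].isna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise FormatError(f"{path}: non-numeric value in column "
                              f"{c!r} at line {line}")
        df[c] = coerced
    return df


def read_raw(path, subject_id: str | None = None,
             nominal_rate: float = 10.0) -> TriaxialRecording:
    """Read a raw acceleration CSV (timestamp_ms,x,y,z)."""
    df = _read_table(path, RAW_COLUMNS)
    return TriaxialRecording(
        subject_id=subject_id or Path(path).stem,
        timestamps=df["timestamp_ms"].to_numpy(np.int64),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        z=df["z"].to_numpy(float),
        nominal_rate=nominal_rate,
    )


def write_raw(rec: TriaxialRecording, path) -> None:
    """Write a raw acceleration CSV; round trips losslessly via repr
    precision."""
    df = pd.DataFrame({
        "timestamp_ms": rec.timestamps,
        "x": rec.x, "y": rec.y, "z": rec.z,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_activity(path) -> ActivitySeries:
    """Read an epoch activity CSV holding a single method."""
    df = _read_table(path, ACTIVITY_COLUMNS)
    methods = df["method"].unique()
    if len(methods) != 1:
        raise FormatError(f"{path}: expected a single method, found "
                          f"{list(methods)}")
    starts = df["epoch_start_ms"].to_numpy(np.int64)
    steps = np.diff(starts)
    epoch_length = int(steps[0] // 1000) if len(steps) else 60
    return ActivitySeries(
        method=str(methods[0]),
        epoch_length=epoch_length,
        epoch_starts=starts,
        values=df["value"].to_numpy(float),
    )


def write_activity(series: ActivitySeries, path) -> None:
    df = pd.DataFrame({
        "epoch_start_ms": series.epoch_starts,
        "value": series.values,
        "method": series.method,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def regularize_timestamps(rec: TriaxialRecording,
                          rate: float | None = None
                          ) -> Tuple[TriaxialRecording, GapReport]:
    """Snap samples to the exact 1000/rate ms grid anchored at the first
    sample.

    Each grid slot takes the nearest input sample; when several samples
    snap to the same slot the earliest is kept; runs of empty slots are
    filled by repeating the previous sample and reported as gap events.
    """
    if len(rec) == 0:
        raise FormatError("cannot regularize an empty recording")
    rate = float(rate if rate is not None else rec.nominal_rate)
    if rate <= 0:
        raise FormatError("rate must be positive")
    step = 1000.0 / rate
    t0 = int(rec.timestamps[0])
    slot = np.round((rec.timestamps - t0) / step).astype(np.int64)
    n_slots = int(slot[-1]) + 1
    # first occurrence per slot == earliest sample (timestamps nondecreasing)
    uniq, first_pos = np.unique(slot, return_index=True)
    slot_src = np.full(n_slots, -1, dtype=np.int64)
    slot_src[uniq] = first_pos
    empty = slot_src < 0
    if empty.any():
        # forward-fill from the previous occupied slot (slot 0 is occupied)
        occupied = np.flatnonzero(~empty)
        ff = occupied[np.searchsorted(occupied, np.arange(n_slots),
                                      side="right") - 1]
        src = slot_src[ff]
        n_events = int(np.count_nonzero(np.diff(empty.astype(np.int8)) == 1)
                       + (1 if empty[0] else 0))
        report = GapReport(n_gap_events=n_events,
                           n_filled=int(empty.sum()))
    else:
        src = slot_src
        report = GapReport()
    new_ts = t0 + np.round(np.arange(n_slots) * step).astype(np.int64)
    out = TriaxialRecording(
        subject_id=rec.subject_id,
        timestamps=new_ts,
        x=rec.x[src], y=rec.y[src], z=rec.z[src],
        nominal_rate=rate,
    )
    return out, report


def _still_points(rec: TriaxialRecording, window_s: float,
                  sd_threshold: float) -> np.ndarray:
    """Mean acceleration vectors of non-overlapping windows whose
    per-axis SD is below the stillness threshold."""
    spe = int(round(window_s * rec.nominal_rate))
    n_win = len(rec) // spe
    if n_win == 0:
        return np.empty((0, 3))
    xyz = rec.xyz[: n_win * spe].reshape(n_win, spe, 3)
    sds = xyz.std(axis=1)
    still = np.all(sds < sd_threshold, axis=1)
    return xyz.mean(axis=1)[still]


def sphere_calibrate(rec: TriaxialRecording,
                     sd_threshold: float = 0.013,
                     window_s: float = 10.0,
                     min_still: int = 10,
                     min_spread_deg: float = 15.0,
                     max_points: int = 2000,
                     ) -> Tuple[TriaxialRecording, CalibrationReport]:
    """Estimate per-axis offsets and scales so that still-period
    acceleration norms approach 1 g, and apply them.

    The model is ``corrected = (raw - offset) / scale``, fitted by
    least squares over the mean vectors of still windows (per-axis
    rolling SD below ``sd_threshold``). When too few still windows
    exist, or their orientations lack diversity (angular spread below
    ``min_spread_deg``), the recording is returned unchanged with
    ``calibrated=False``. The fit is only applied when it does not
    increase the RMS deviation of still-point norms from 1 g.
    """
    pts = _still_points(rec, window_s, sd_threshold)
    report = CalibrationReport(n_still=len(pts))
    norms = np.linalg.norm(pts, axis=1) if len(pts) else np.empty(0)
    if len(pts) < min_still or np.any(norms < 1e-6):
        report.residual = float(np.sqrt(np.mean((norms - 1.0) ** 2))) if len(pts) else np.nan
        return rec, report
    units = pts / norms[:, None]
    mean_dir = units.mean(axis=0)
    mn = np.linalg.norm(mean_dir)
    spread = 0.0
    if mn > 1e-9:
        cosang = np.clip(units @ (mean_dir / mn), -1.0, 1.0)
        spread = float(np.degrees(np.max(np.arccos(cosang))))
    else:
        spread = 180.0
    resid_before = float(np.sqrt(np.mean((norms - 1.0) ** 2)))
    report.residual = resid_before
    if spread < min_spread_deg:
        return rec, report

    if len(pts) > max_points:
        sel = np.linspace(0, len(pts) - 1, max_points).astype(int)
        pts = pts[sel]

    def residuals(p):
        o, s = p[:3], p[3:]
        return np.linalg.norm((pts - o) / s, axis=1) - 1.0

    fit = least_squares(residuals, x0=np.array([0, 0, 0, 1, 1, 1.0]))
    offsets, scales = fit.x[:3], fit.x[3:]
    if np.any(scales <= 0):
        return rec, report
    resid_after = float(np.sqrt(np.mean(residuals(fit.x) ** 2)))
    if resid_after > resid_before:
        return rec, report  # never make still-point norms worse
    out = TriaxialRecording(
        subject_id=rec.subject_id,
        timestamps=rec.timestamps.copy(),
        x=(rec.x - offsets[0]) / scales[0],
        y=(rec.y - offsets[1]) / scales[1],
        z=(rec.z - offsets[2]) / scales[2],
        nominal_rate=rec.nominal_rate,
    )
    report = CalibrationReport(offsets=offsets, scales=scales,
                               residual=resid_after, n_still=report.n_still,
                               calibrated=True)
    return out, report
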