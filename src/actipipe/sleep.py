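"""Sleep-wake scoring.

Two complementary scorers are provided, both aimed at consolidated
sleep rather than epoch-accurate staging:

* a trend-threshold scorer for epoch activity data (Munich-style):
  an epoch is provisionally sleep when its activity falls below a
  fraction of the centered 24 h moving-average trend, then a two-stage
  rescoring consolidates the classification (short wake gaps flanked by
  sleep are bridged, then short sleep bouts are discarded);
* a z-angle scorer for raw acceleration: sustained inactivity bouts
  (SIB; wrist-angle change staying within 5 degrees for at least 5 min)
  intersected with a single contiguous sleep-period-time (SPT) window
  per noon-to-noon day found from the rolling median of absolute angle
  changes.

Both emit labels on a common 60 s epoch grid so their sleep segments
can be compared with interval overlap measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .core import ActivitySeries, ConfigurationError, TriaxialRecording

MS_PER_DAY = 86_400_000
NOON_MS = 43_200_000


@dataclass
class SleepScore:
    """Per-epoch sleep labels plus the maximal sleep segments."""

    epoch_length: int
    epoch_starts: np.ndarray
    labels: np.ndarray                       # bool, True = sleep
    segments: List[Tuple[int, int]] = field(default_factory=list)  # ms
    algorithm: str = ""
    parameters: dict = field(default_factory=dict)


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open index runs [i0, i1) where mask is True."""
    if len(mask) == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _segments_from_labels(labels: np.ndarray, epoch_starts: np.ndarray,
                          epoch_length: int) -> List[Tuple[int, int]]:
    step = epoch_length * 1000
    return [(int(epoch_starts[i0]), int(epoch_starts[i1 - 1]) + step)
            for i0, i1 in _runs(labels)]


def _rescore(raw: np.ndarray, epoch_length: int,
             gap_min: float, bout_min: float) -> np.ndarray:
    """Two-stage rescoring: bridge short wake gaps flanked by sleep,
    then drop short sleep bouts. Idempotent as a whole."""
    labels = raw.copy()
    gap_epochs = int(round(gap_min * 60 / epoch_length))
    bout_epochs = int(round(bout_min * 60 / epoch_length))
    n = len(labels)
    for i0, i1 in _runs(~labels):
        flanked = i0 > 0 and i1 < n
        if flanked and (i1 - i0) < gap_epochs:
            labels[i0:i1] = True
    for i0, i1 in _runs(labels):
        if (i1 - i0) < bout_epochs:
            labels[i0:i1] = False
    return labels


def _trend(values: np.ndarray, epoch_length: int) -> np.ndarray:
    """Centered 24 h moving average; the window is truncated to the
    available samples near the edges (always at least 12 h there)."""
    half = int(round(12 * 3600 / epoch_length))
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def masda_score(activity: ActivitySeries, threshold_frac: float = 0.25,
                gap_min: float = 30.0, bout_min: float = 30.0) -> SleepScore:
    """Trend-threshold sleep scoring of an epoch activity series.

    ``threshold_frac`` is the fraction of the 24 h trend below which an
    epoch is provisionally scored sleep (the recommended 25% default).
    """
    span_s = len(activity) * activity.epoch_length
    if span_s < 24 * 3600:
        raise ConfigurationError("trend-threshold scoring needs >= 24 h of data")
    trend = _trend(activity.values, activity.epoch_length)
    raw = activity.values < threshold_frac * trend
    labels = _rescore(raw, activity.epoch_length, gap_min, bout_min)
    return SleepScore(
        epoch_length=activity.epoch_length,
        epoch_starts=activity.epoch_starts,
        labels=labels,
        segments=_segments_from_labels(labels, activity.epoch_starts,
                                       activity.epoch_length),
        algorithm="masda",
        parameters={"threshold_frac": threshold_frac, "gap_min": gap_min,
                    "bout_min": bout_min, "input": activity.method},
    )


def _block_angles(rec: TriaxialRecording, block_s: float = 5.0) -> np.ndarray:
    """Z-angle (degrees) per consecutive block: per-axis rolling medians
    over one block length, converted to the angle between the z axis and
    the horizontal plane, then averaged per block."""
    win = max(int(round(block_s * rec.nominal_rate)), 1)
    med = [ndimage.median_filter(a, size=win, mode="nearest")
           for a in (rec.x, rec.y, rec.z)]
    angle = np.degrees(np.arctan2(
        med[2], np.sqrt(med[0] ** 2 + med[1] ** 2)))
    n_blocks = len(angle) // win
    return angle[: n_blocks * win].reshape(n_blocks, win).mean(axis=1)


def vanhees_score(rec: TriaxialRecording, spt_threshold: float = 0.4,
                  angle_tol_deg: float = 5.0, sib_min_min: float = 5.0,
                  spt_block_min: float = 30.0, spt_gap_max_min: float = 60.0,
                  block_s: float = 5.0, epoch_length: int = 60) -> SleepScore:
    """Z-angle sleep scoring of a regularized triaxial recording.

    Sleep is the intersection of sustained inactivity bouts with the
    per-day (noon-to-noon) sleep-period-time window; ``spt_threshold``
    is the fixed threshold (degrees) on the 5-min rolling median of
    absolute successive angle changes that seeds SPT candidate blocks.
    """
    span_ms = int(rec.timestamps[-1] - rec.timestamps[0])
    if span_ms < MS_PER_DAY:
        raise ConfigurationError(
            "z-angle scoring needs at least one noon-to-noon day")
    angles = _block_angles(rec, block_s)
    n_blocks = len(angles)
    dangle = np.abs(np.diff(angles))
    # change assigned to the later block; block 0 has no change
    change = np.concatenate([[0.0], dangle])

    # --- sustained inactivity bouts ---
    stable = change < angle_tol_deg
    stable[0] = True
    min_blocks = int(round(sib_min_min * 60 / block_s))
    sib = np.zeros(n_blocks, dtype=bool)
    for i0, i1 in _runs(stable):
        if i1 - i0 >= min_blocks:
            sib[i0:i1] = True

    # --- single contiguous SPT per noon-to-noon day ---
    med_win = int(round(sib_min_min * 60 / block_s))
    rolled = ndimage.median_filter(change, size=med_win, mode="nearest")
    cand = rolled < spt_threshold
    block_t0 = int(rec.timestamps[0])
    block_ms = int(block_s * 1000)
    block_times = block_t0 + np.arange(n_blocks, dtype=np.int64) * block_ms
    day_idx = (block_times - NOON_MS) // MS_PER_DAY
    keep_blocks = int(round(spt_block_min * 60 / block_s))
    bridge_blocks = int(round(spt_gap_max_min * 60 / block_s))
    spt = np.zeros(n_blocks, dtype=bool)
    for d in np.unique(day_idx):
        sel = np.flatnonzero(day_idx == d)
        runs = [(i0, i1) for i0, i1 in _runs(cand[sel])
                if i1 - i0 >= keep_blocks]
        if not runs:
            continue
        # bridge gaps shorter than the limit, keep the longest merged run
        merged = [list(runs[0])]
        for i0, i1 in runs[1:]:
            if i0 - merged[-1][1] < bridge_blocks:
                merged[-1][1] = i1
            else:
                merged.append([i0, i1])
        i0, i1 = max(merged, key=lambda r: r[1] - r[0])
        spt[sel[i0]:sel[i1 - 1] + 1] = True

    sleep_blocks = sib & spt

    # --- emit on the 60 s epoch grid ---
    epoch_ms = epoch_length * 1000
    first_epoch = -(-block_t0 // epoch_ms) * epoch_ms
    bpe = epoch_ms // block_ms
    start_block = int((first_epoch - block_t0) // block_ms)
    n_ep = (n_blocks - start_block) // bpe
    if n_ep < 1:
        raise ConfigurationError("recording shorter than one epoch")
    ep = sleep_blocks[start_block:start_block + n_ep * bpe].reshape(n_ep, bpe)
    labels = ep.sum(axis=1) * 2 >= bpe
    epoch_starts = first_epoch + np.arange(n_ep, dtype=np.int64) * epoch_ms
    return SleepScore(
        epoch_length=epoch_length,
        epoch_starts=epoch_starts,
        labels=labels,
        segments=_segments_from_labels(labels, epoch_starts, epoch_length),
        algorithm="vanhees",
        parameters={"spt_threshold": spt_threshold,
                    "angle_tol_deg": angle_tol_deg,
                    "sib_min_min": sib_min_min,
                    "spt_block_min": spt_block_min,
                    "spt_gap_max_min": spt_gap_max_min,
                    "block_s": block_s},
    )


def total_sleep_time(score: SleepScore) -> float:
    """Total sleep time in hours (summed segment durations)."""
    return sum(e - s for s, e in score.segments) / 3_600_000.0
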