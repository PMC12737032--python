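"""Device-specific activity determinations.

Two devices need dedicated emulators:

* MW - CamNtech MotionWatch-style counts: per-axis band-pass, Euclidean
  norm, per-clock-second peak, and the per-epoch sum of peaks exceeding
  0.1 g. The device's native 3-11 Hz band cannot be realized at a 10 Hz
  sampling rate, so the generalized 0.25-2.5 Hz band-pass stands in.
* AC - Ametris/ActiGraph-style activity counts: per-axis resampling to
  30 Hz, a narrow band-pass, rectification, dynamic-range clipping, a
  deadband, coarse quantization, decimation to 10 Hz, and a per-epoch
  sum; the three per-axis epoch sums are combined as their Euclidean
  norm (vector magnitude counts). The stage constants live in
  ``AC_PARAMS`` and follow the openly documented count pipeline; the
  result is an emulation, not a bit-exact clone of any release.

The remaining devices map onto generalized methods: ZCM/TAT/PIM on
FMpre (Condor ActTrust, and the classic AMI metrics) and PIM on ENMO
with 60 s epochs (the GGIR default pipeline).
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from scipy import signal as sps

from .core import ActivitySeries, ConfigurationError, TriaxialRecording
from .metrics import ThresholdSpec, compute_activity, compute_threshold
from .preprocess import bandpass_sos, preprocess

MW_PEAK_THRESHOLD_G = 0.1

#: Stage constants of the counts emulation, pinned in one block so they
#: can be corrected against a specific vendor release without touching code.
AC_PARAMS = {
    "resample_hz": 30.0,
    "band_hz": (0.29, 1.63),
    "band_order": 3,
    "ceiling_g": 2.13,       # dynamic-range clip after filtering
    "deadband_g": 0.068,     # values below contribute zero counts
    "resolution_g": 1.0 / 128.0,  # one count unit
    "decimate_to_hz": 10.0,
}


def mw_epoch_sums(per_second_peaks: np.ndarray, epoch_length: int,
                  threshold: float = MW_PEAK_THRESHOLD_G) -> np.ndarray:
    """Sum, within each epoch, the per-second peaks that exceed the
    threshold. Pure helper so the summation rule is testable directly."""
    peaks = np.asarray(per_second_peaks, dtype=float)
    n_ep = len(peaks) // epoch_length
    seg = peaks[: n_ep * epoch_length].reshape(n_ep, epoch_length)
    kept = np.where(seg > threshold, seg, 0.0)
    return kept.sum(axis=1)


def emulate_mw(rec: TriaxialRecording, epoch_length: int = 60,
               zero_phase: bool = False) -> ActivitySeries:
    """MotionWatch-style counts from a regularized recording."""
    rate = rec.nominal_rate
    if rate < 2:
        raise ConfigurationError("MW emulation requires >= 2 samples/s")
    fm = preprocess(rec, "FMpre", zero_phase=zero_phase)
    # clock-second alignment: start at the first whole second on the grid
    t0 = int(rec.timestamps[0])
    first_sec = -(-t0 // 1000) * 1000
    start_idx = int(round((first_sec - t0) * rate / 1000.0))
    sps_n = int(round(rate))
    n_sec = (len(fm) - start_idx) // sps_n
    if n_sec < epoch_length:
        raise ConfigurationError("recording shorter than one epoch")
    per_sec = fm.values[start_idx:start_idx + n_sec * sps_n]
    peaks = per_sec.reshape(n_sec, sps_n).max(axis=1)
    # epoch grid: first whole multiple of epoch_length at/after first_sec
    epoch_ms = epoch_length * 1000
    first_epoch = -(-first_sec // epoch_ms) * epoch_ms
    sec_off = (first_epoch - first_sec) // 1000
    peaks = peaks[sec_off:]
    vals = mw_epoch_sums(peaks, epoch_length)
    starts = first_epoch + np.arange(len(vals), dtype=np.int64) * epoch_ms
    return ActivitySeries(method="MW", epoch_length=epoch_length,
                          epoch_starts=starts, values=vals)


def _ac_axis_counts(axis: np.ndarray, rate: float, params: dict) -> np.ndarray:
    """Counts pipeline for one axis; returns per-sample count values at
    the decimated rate. Every stage is monotone in |input| amplitude."""
    n = len(axis)
    dur = n / rate
    up_n = int(round(dur * params["resample_hz"]))
    t_src = np.arange(n) / rate
    t_up = np.arange(up_n) / params["resample_hz"]
    up = np.interp(t_up, t_src, axis)
    sos = sps.butter(params["band_order"], list(params["band_hz"]),
                     btype="bandpass", fs=params["resample_hz"], output="sos")
    zi = sps.sosfilt_zi(sos) * up[0]  # steady-state start, no DC transient
    filt, _ = sps.sosfilt(sos, up, zi=zi)
    np.abs(filt, out=filt)
    filt = np.minimum(filt, params["ceiling_g"])
    filt[filt < params["deadband_g"]] = 0.0
    counts = np.floor(filt / params["resolution_g"])
    dec = int(round(params["resample_hz"] / params["decimate_to_hz"]))
    return counts[::dec]


def emulate_ac(rec: TriaxialRecording, epoch_length: int = 60,
               params: Optional[dict] = None) -> ActivitySeries:
    """Activity-count emulation; per-axis epoch sums combined as their
    Euclidean norm."""
    params = dict(AC_PARAMS, **(params or {}))
    rate = rec.nominal_rate
    dec_rate = params["decimate_to_hz"]
    t0 = int(rec.timestamps[0])
    epoch_ms = epoch_length * 1000
    first_epoch = -(-t0 // epoch_ms) * epoch_ms
    start_idx = int(round((first_epoch - t0) * dec_rate / 1000.0))
    spe = int(round(epoch_length * dec_rate))
    axis_sums = []
    for axis in (rec.x, rec.y, rec.z):
        c = _ac_axis_counts(axis, rate, params)
        n_ep = (len(c) - start_idx) // spe
        if n_ep < 1:
            raise ConfigurationError("recording shorter than one epoch")
        seg = c[start_idx:start_idx + n_ep * spe].reshape(n_ep, spe)
        axis_sums.append(seg.sum(axis=1))
    sums = np.stack(axis_sums)
    vals = np.sqrt((sums ** 2).sum(axis=0))
    starts = first_epoch + np.arange(sums.shape[1], dtype=np.int64) * epoch_ms
    return ActivitySeries(method="AC", epoch_length=epoch_length,
                          epoch_starts=starts, values=vals)


#: Labels of the six device-linked activity determinations, in the order
#: they are reported.
DEVICE_SUITE_LABELS = ("PIM(FMpre)", "ZCM(FMpre)", "TAT(FMpre)",
                       "PIM(ENMO)", "AC", "MW")


def device_suite(rec: TriaxialRecording, epoch_length: int = 60,
                 fmpre_threshold: Optional[ThresholdSpec] = None,
                 zero_phase: bool = False) -> List[ActivitySeries]:
    """The six device-linked activity series for one recording.

    ``fmpre_threshold`` supplies a cohort-pooled SD threshold for
    ZCM/TAT; when omitted it is computed from this recording alone.
    """
    fmpre = preprocess(rec, "FMpre", zero_phase=zero_phase)
    enmo = preprocess(rec, "ENMO", zero_phase=zero_phase)
    thr = fmpre_threshold or compute_threshold(fmpre, basis="per_recording")
    out = [
        compute_activity(fmpre, "PIM", epoch_length),
        compute_activity(fmpre, "ZCM", epoch_length, threshold=thr),
        compute_activity(fmpre, "TAT", epoch_length, threshold=thr),
        compute_activity(enmo, "PIM", epoch_length),
        emulate_ac(rec, epoch_length),
        emulate_mw(rec, epoch_length, zero_phase=zero_phase),
    ]
    assert [s.method for s in out] == list(DEVICE_SUITE_LABELS)
    return out
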