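"""Nonparametric circadian rhythm analysis (NPCRA).

Five indicators are computed from multi-day activity (or gravity-free
acceleration) series:

* L5 / M10 - the least-active 5 h and most-active 10 h circular windows
  of the 24 h mean profile, each with an onset (seconds since midnight)
  and a mean value. The profile averages each time-of-day bin across
  complete midnight-to-midnight days; the window slides in one-minute
  steps and may wrap midnight.
* RA - relative amplitude, (M10val - L5val) / (M10val + L5val), in [0, 1].
* IS - interdaily stability: the variance of the 24 h hourly mean profile
  divided by the variance of the hourly series, in [0, 1]; 1 for an
  exactly 24 h-periodic series, about 1/(number of days) for white noise.
* IV - intradaily variability: the mean squared successive difference of
  the hourly series divided by its variance, in [0, 2]; near 2 for white
  noise, small for a slowly varying diurnal pattern.

Indicators can be derived directly from preprocessed acceleration when
the scheme has a non-constant mean: FMpre, HFMpre, UFNM and ENMO
directly; FX, FY, FZ and FMpost only after rectification; UFM never
(its mean converges to Earth's gravitational constant, 1 g). For
acceleration input the 24 h profile is built at 1 s resolution instead
of the 60 s used for epoch-level activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

from .core import (ActivitySeries, ConfigurationError, PreprocessedSignal,
                   UndefinedValueError)

SECONDS_PER_DAY = 86400
MS_PER_DAY = 86_400_000

#: Acceleration schemes admissible for NPCRA without rectification.
DIRECT_SCHEMES = frozenset({"FMpre", "HFMpre", "UFNM", "ENMO"})
#: Acceleration schemes admissible only after rectification.
RECTIFY_FIRST = frozenset({"FX", "FY", "FZ", "FMpost"})


@dataclass
class DailyProfile:
    """24 h mean profile: each bin is the across-days mean of one
    time-of-day bin, over complete midnight-to-midnight days."""

    bin_length: int           # seconds
    bins: np.ndarray          # length 86400 / bin_length
    n_days_used: int

    def __post_init__(self):
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bin_length * len(self.bins) != SECONDS_PER_DAY:
            raise ConfigurationError("bin count x bin_length must equal 86400 s")


@dataclass
class WindowDesignation:
    """A circular L-hour window of the daily profile."""

    onset_s: int              # seconds since midnight, [0, 86400)
    length_h: float           # 5 or 10
    mean_value: float

    @property
    def onset_hhmm(self) -> str:
        h, rem = divmod(self.onset_s, 3600)
        return f"{h:02d}:{rem // 60:02d}"


@dataclass
class NPCRAResult:
    l5: WindowDesignation
    m10: WindowDesignation
    ra: float
    is_: float
    iv: float
    method: str
    normalized: bool
    n_days_used: int

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "normalized": self.normalized,
            "n_days_used": self.n_days_used,
            "L5_onset_s": int(self.l5.onset_s), "L5_value": self.l5.mean_value,
            "M10_onset_s": int(self.m10.onset_s), "M10_value": self.m10.mean_value,
            "RA": self.ra, "IS": self.is_, "IV": self.iv,
        }


def _series_arrays(obj: Union[PreprocessedSignal, ActivitySeries]):
    if isinstance(obj, ActivitySeries):
        return obj.values, obj.epoch_starts, obj.epoch_length * 1000.0
    if isinstance(obj, PreprocessedSignal):
        return obj.values, obj.timestamps, 1000.0 / obj.rate
    raise ConfigurationError(f"unsupported series type {type(obj).__name__}")


def _complete_day_mask(timestamps: np.ndarray, dt_ms: float
                       ) -> Tuple[np.ndarray, int]:
    """Boolean mask of samples belonging to complete midnight-to-midnight
    days, and the number of such days."""
    day = timestamps // MS_PER_DAY
    expected = int(round(MS_PER_DAY / dt_ms))
    uniq, counts = np.unique(day, return_counts=True)
    complete = set(uniq[counts == expected].tolist())
    if not complete:
        raise ConfigurationError(
            "series does not span a complete midnight-to-midnight day")
    mask = np.isin(day, list(complete))
    return mask, len(complete)


def mean_profile(obj: Union[PreprocessedSignal, ActivitySeries],
                 bin_length: int) -> DailyProfile:
    """24 h mean profile at the requested bin length (seconds)."""
    if SECONDS_PER_DAY % bin_length:
        raise ConfigurationError("bin_length must divide 86400")
    values, timestamps, dt_ms = _series_arrays(obj)
    if bin_length * 1000 % int(round(dt_ms)):
        raise ConfigurationError("bin_length must be a multiple of the "
                                 "sample/epoch interval")
    mask, n_days = _complete_day_mask(timestamps, dt_ms)
    v = values[mask]
    t = timestamps[mask]
    n_bins = SECONDS_PER_DAY // bin_length
    b = (t % MS_PER_DAY) // (bin_length * 1000)
    sums = np.bincount(b, weights=v, minlength=n_bins)
    counts = np.bincount(b, minlength=n_bins)
    return DailyProfile(bin_length=bin_length, bins=sums / counts,
                        n_days_used=n_days)


def locate_l5_m10(profile: DailyProfile, step_s: int = 60
                  ) -> Tuple[WindowDesignation, WindowDesignation]:
    """Least-active 5 h and most-active 10 h windows of the profile.

    Onsets advance in ``step_s`` steps (one minute by default, also for
    1 s profiles), windows wrap midnight, ties resolve to the earliest
    onset.
    """
    bl = profile.bin_length
    if step_s % bl:
        raise ConfigurationError("step_s must be a multiple of bin_length")
    bins = profile.bins
    n = len(bins)
    csum = np.concatenate([[0.0], np.cumsum(np.concatenate([bins, bins]))])
    onsets = np.arange(0, n, step_s // bl)

    def window(hours: float, pick) -> WindowDesignation:
        w = int(round(hours * 3600 / bl))
        means = (csum[onsets + w] - csum[onsets]) / w
        i = int(pick(means))
        return WindowDesignation(onset_s=int(onsets[i] * bl),
                                 length_h=hours,
                                 mean_value=float(means[i]))

    return window(5, np.argmin), window(10, np.argmax)


def relative_amplitude(m10val: float, l5val: float) -> float:
    """RA = (M10val - L5val) / (M10val + L5val)."""
    if m10val < l5val or l5val < 0:
        raise ConfigurationError("require m10val >= l5val >= 0")
    if m10val + l5val == 0:
        raise UndefinedValueError("RA undefined: M10 and L5 are both zero")
    return (m10val - l5val) / (m10val + l5val)


def hourly_means(obj: Union[PreprocessedSignal, ActivitySeries]) -> np.ndarray:
    """Clock-hour means over complete days, the x_i series behind IS/IV."""
    values, timestamps, dt_ms = _series_arrays(obj)
    mask, _ = _complete_day_mask(timestamps, dt_ms)
    v = values[mask]
    t = timestamps[mask]
    hour = t // 3_600_000
    # relabel to consecutive order (complete days may be non-adjacent)
    _, inv = np.unique(hour, return_inverse=True)
    sums = np.bincount(inv, weights=v)
    counts = np.bincount(inv)
    return sums / counts


def _is_iv(hourly: np.ndarray) -> Tuple[float, float]:
    x = np.asarray(hourly, dtype=float)
    n = len(x)
    if n % 24:
        raise ConfigurationError("hourly series must cover whole days")
    xm = x.mean()
    denom = ((x - xm) ** 2).mean()
    if denom == 0:
        raise UndefinedValueError("IS/IV undefined for a zero-variance series")
    profile = x.reshape(-1, 24).mean(axis=0)
    is_ = float(((profile - xm) ** 2).mean() / denom)
    iv = float((np.diff(x) ** 2).sum() / (n - 1) / denom)
    return is_, iv


def interdaily_stability(hourly: np.ndarray) -> float:
    """IS: variance of the 24 h hourly profile over the series variance."""
    return _is_iv(hourly)[0]


def intradaily_variability(hourly: np.ndarray) -> float:
    """IV: mean squared successive difference over the series variance."""
    return _is_iv(hourly)[1]


def npcra_from_signal(obj: Union[PreprocessedSignal, ActivitySeries],
                      normalize: bool = True,
                      step_s: int = 60) -> NPCRAResult:
    """Full NPCRA of one activity series or admissible acceleration
    signal.

    With ``normalize`` the series is divided by its grand mean before the
    profile/window step, removing the value-range differences between
    determination methods; RA, IS and IV are scale-invariant either way.
    """
    if isinstance(obj, PreprocessedSignal):
        if obj.scheme == "UFM":
            raise ConfigurationError(
                "NPCRA is undefined on UFM: averaging windows of raw "
                "magnitude converges to Earth's gravitational constant "
                "(1 g), a constant mean")
        if obj.scheme in RECTIFY_FIRST and not obj.rectified:
            raise ConfigurationError(
                f"{obj.scheme} is near-symmetric about 0 g; rectify() it "
                "before NPCRA")
        if obj.scheme not in DIRECT_SCHEMES | RECTIFY_FIRST:
            raise ConfigurationError(
                f"NPCRA not applicable to scheme {obj.scheme!r}")
        bin_length = 1
        method = obj.label
        label_values = obj.values
    else:
        bin_length = min(obj.epoch_length, 60)
        method = obj.method
        label_values = obj.values

    if normalize:
        grand = float(label_values.mean())
        if grand == 0:
            raise UndefinedValueError("cannot normalize a zero-mean series")
        if isinstance(obj, PreprocessedSignal):
            obj = PreprocessedSignal(obj.scheme, obj.values / grand,
                                     obj.timestamps, obj.rate, obj.rectified)
        else:
            obj = ActivitySeries(obj.method, obj.epoch_length,
                                 obj.epoch_starts, obj.values / grand)

    profile = mean_profile(obj, bin_length)
    l5, m10 = locate_l5_m10(profile, step_s=step_s)
    ra = relative_amplitude(m10.mean_value, l5.mean_value)
    hourly = hourly_means(obj)
    is_, iv = _is_iv(hourly)
    return NPCRAResult(l5=l5, m10=m10, ra=ra, is_=is_, iv=iv,
                       method=method, normalized=normalize,
                       n_days_used=profile.n_days_used)
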