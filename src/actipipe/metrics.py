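"""Activity metrics: compress preprocessed acceleration into one value
per fixed-length epoch.

Six generalized metrics are provided:

* PIM  - proportional integration, sum of |value|*dt per epoch (g*s);
* ZCM  - number of upward crossings of a fixed threshold level;
* TAT  - time spent above the threshold level (s);
* MAD  - mean absolute deviation about the epoch mean (g);
* AI   - activity index, sqrt of the mean over the three axes of the
  systematic (above-noise) per-axis epoch variance (g);
* HFEN - epoch mean of the high-pass-filtered magnitude (g).

The intersection threshold for ZCM/TAT is set to the standard deviation
of all the preprocessed acceleration data (for UFM, 1 g is added to
account for the gravity component still present in that scheme).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np

from .core import (ActivitySeries, AxisBundle, ConfigurationError,
                   PreprocessedSignal, SCHEME_FAMILY)

METRICS = ("PIM", "ZCM", "TAT", "MAD", "AI", "HFEN")
THRESHOLD_METRICS = frozenset({"ZCM", "TAT"})


@dataclass
class ThresholdSpec:
    """Intersection threshold for ZCM/TAT on one preprocessing scheme."""

    level: float            # g
    basis: str              # "pooled" or "per_recording"
    scheme: str

    def __post_init__(self):
        if self.level <= 0:
            raise ConfigurationError("threshold level must be positive")
        if self.basis not in ("pooled", "per_recording"):
            raise ConfigurationError("basis must be pooled or per_recording")


def compute_threshold(signals: Union[PreprocessedSignal,
                                     Sequence[PreprocessedSignal]],
                      basis: str = "pooled") -> ThresholdSpec:
    """SD-rule threshold over the pooled samples of the given signals.

    All signals must share one scheme. For UFM the level is 1 g + SD,
    since the gravity component keeps that scheme's mean near 1 g.
    """
    if isinstance(signals, PreprocessedSignal):
        signals = [signals]
    signals = list(signals)
    if not signals:
        raise ConfigurationError("compute_threshold needs at least one signal")
    schemes = {s.scheme for s in signals}
    if len(schemes) > 1:
        raise ConfigurationError(f"mixed schemes in threshold pool: {schemes}")
    scheme = schemes.pop()
    pooled = np.concatenate([s.values for s in signals])
    sd = float(pooled.std())
    level = 1.0 + sd if scheme == "UFM" else sd
    return ThresholdSpec(level=level, basis=basis, scheme=scheme)


def pooled_sd_from_moments(n: int, total: float, total_sq: float) -> float:
    """SD from streamed moments (population convention, matching
    ``ndarray.std``); lets cohort runs pool the threshold without holding
    every signal in memory."""
    mean = total / n
    var = max(total_sq / n - mean * mean, 0.0)
    return float(np.sqrt(var))


def _epoch_grid(timestamps: np.ndarray, rate: float, epoch_length: int):
    """Index of the first sample on the clock-aligned epoch grid, samples
    per epoch and number of complete epochs."""
    if len(timestamps) == 0:
        raise ConfigurationError("empty signal")
    dt_ms = 1000.0 / rate
    epoch_ms = epoch_length * 1000
    t0 = int(timestamps[0])
    first_start = -(-t0 // epoch_ms) * epoch_ms  # ceil to the grid
    start_idx = int(round((first_start - t0) / dt_ms))
    spe = int(round(epoch_length * rate))
    if spe < 1:
        raise ConfigurationError("epoch shorter than one sample interval")
    n_ep = (len(timestamps) - start_idx) // spe
    if n_ep < 1:
        raise ConfigurationError("signal shorter than one complete epoch")
    starts = first_start + np.arange(n_ep, dtype=np.int64) * epoch_ms
    return start_idx, spe, n_ep, starts


def _count_upward_crossings(epochs: np.ndarray, level: float) -> np.ndarray:
    """Upward crossings of the level within each epoch row: sample i-1 at
    or below the level, sample i above it."""
    below = epochs[:, :-1] <= level
    above = epochs[:, 1:] > level
    return np.count_nonzero(below & above, axis=1).astype(float)


def compute_activity(sig: Union[PreprocessedSignal, AxisBundle],
                     metric: str,
                     epoch_length: int = 60,
                     threshold: Optional[ThresholdSpec] = None,
                     noise_variance: float = 0.0) -> ActivitySeries:
    """Aggregate a preprocessed signal into epoch activity values.

    Partial leading/trailing epochs are dropped; epochs are anchored on
    clock boundaries that are whole multiples of ``epoch_length``.
    ``noise_variance`` is the AI metric's device noise term (sigma_0^2,
    in g^2); it defaults to 0 as no calibrated value is assumed.
    """
    if metric not in METRICS:
        raise ConfigurationError(f"unknown metric {metric!r}")
    if metric == "AI":
        if not isinstance(sig, AxisBundle):
            raise ConfigurationError("AI requires a triaxial AxisBundle")
        start_idx, spe, n_ep, starts = _epoch_grid(sig.timestamps, sig.rate,
                                                   epoch_length)
        axes = np.stack([sig.x, sig.y, sig.z])  # (3, n)
        seg = axes[:, start_idx:start_idx + n_ep * spe].reshape(3, n_ep, spe)
        var = seg.var(axis=2)                   # (3, n_ep)
        vals = np.sqrt(np.maximum(var - noise_variance, 0.0).mean(axis=0))
        return ActivitySeries(method=f"AI({sig.scheme})",
                              epoch_length=epoch_length,
                              epoch_starts=starts, values=vals)

    if isinstance(sig, AxisBundle):
        raise ConfigurationError(f"{metric} operates on a single-channel signal")
    if metric == "HFEN" and sig.scheme != "HFMpre":
        raise ConfigurationError("HFEN is defined only on the HFMpre scheme")
    if metric in THRESHOLD_METRICS:
        if threshold is None:
            raise ConfigurationError(f"{metric} requires a ThresholdSpec")
        if threshold.scheme != sig.scheme:
            raise ConfigurationError(
                f"threshold was computed on {threshold.scheme!r}, "
                f"signal is {sig.scheme!r}")
    start_idx, spe, n_ep, starts = _epoch_grid(sig.timestamps, sig.rate,
                                               epoch_length)
    seg = sig.values[start_idx:start_idx + n_ep * spe].reshape(n_ep, spe)
    dt = 1.0 / sig.rate
    if metric == "PIM":
        vals = np.abs(seg).sum(axis=1) * dt
    elif metric == "ZCM":
        vals = _count_upward_crossings(seg, threshold.level)
    elif metric == "TAT":
        vals = np.count_nonzero(seg > threshold.level, axis=1) * dt
    elif metric == "MAD":
        vals = np.abs(seg - seg.mean(axis=1, keepdims=True)).mean(axis=1)
    else:  # HFEN
        vals = seg.mean(axis=1)
    return ActivitySeries(method=f"{metric}({sig.label})",
                          epoch_length=epoch_length,
                          epoch_starts=starts, values=vals)


@dataclass(frozen=True)
class MethodCombo:
    """One generalized activity determination method: a metric applied
    to a preprocessing scheme, tagged with the scheme's family."""

    metric: str
    scheme: str

    @property
    def label(self) -> str:
        return f"{self.metric}({self.scheme})"

    @property
    def family(self) -> str:
        return SCHEME_FAMILY[self.scheme]


# The roster is reconstructed from the framework's constraints (HFEN only
# on HFMpre, AI only on axis triplets, the four sample-wise metrics on the
# five magnitude-type schemes and the three filtered axes) and kept as a
# single table so it can be corrected in one place.
_SAMPLEWISE = ("PIM", "ZCM", "TAT", "MAD")
_MAGNITUDE_SCHEMES = ("UFM", "UFNM", "ENMO", "FMpre", "FMpost")
_AXIS_SCHEMES = ("FX", "FY", "FZ")


def valid_combinations() -> List[MethodCombo]:
    """The 35 valid metric x preprocessing combinations."""
    combos = [MethodCombo(m, s) for m in _SAMPLEWISE
              for s in _MAGNITUDE_SCHEMES]
    combos += [MethodCombo(m, s) for m in _SAMPLEWISE for s in _AXIS_SCHEMES]
    combos += [MethodCombo("AI", "UFXYZ"), MethodCombo("AI", "FXYZ"),
               MethodCombo("HFEN", "HFMpre")]
    return combos
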