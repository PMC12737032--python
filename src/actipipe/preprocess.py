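"""Preprocessing schemes turning raw triaxial acceleration into the
single-channel signals that activity metrics aggregate.

Two routes remove the static gravity component from the measured
acceleration:

* arithmetically, from the magnitude: ``UFNM = |UFM - 1|`` keeps the
  absolute deviation from 1 g, while ``ENMO = max(UFM - 1, 0)``
  truncates negative deviations to zero;
* by digital filtering: a 3rd-order Butterworth band-pass with
  0.25 and 2.5 Hz cutoffs applied per axis before the Euclidean norm
  (``FX``/``FY``/``FZ`` -> ``FMpre``) or to the magnitude afterwards
  (``FMpost``), and a 4th-order Butterworth high-pass with 0.2 Hz
  cutoff per axis before the norm (``HFMpre``).

Because the Euclidean norm and linear filtering do not commute, FMpre
and FMpost respond differently to posture changes, which is one of the
mechanisms separating preprocessing families downstream.

Filters are applied causally (single pass) by default, emulating
on-device real-time processing; ``zero_phase=True`` switches to
forward-backward filtering.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import (AxisBundle, ConfigurationError, PreprocessedSignal,
                   SCHEMES, TriaxialRecording)

BANDPASS_LOW_HZ = 0.25
BANDPASS_HIGH_HZ = 2.5
BANDPASS_ORDER = 3
HIGHPASS_HZ = 0.2
HIGHPASS_ORDER = 4


def bandpass_sos(rate: float) -> np.ndarray:
    """The generalized wrist-activity band-pass (0.25-2.5 Hz, order 3)."""
    if BANDPASS_HIGH_HZ >= rate / 2:
        raise ConfigurationError(
            f"band-pass cutoff {BANDPASS_HIGH_HZ} Hz is not below the "
            f"Nyquist frequency of a {rate} Hz recording")
    return sps.butter(BANDPASS_ORDER, [BANDPASS_LOW_HZ, BANDPASS_HIGH_HZ],
                      btype="bandpass", fs=rate, output="sos")


def highpass_sos(rate: float) -> np.ndarray:
    if HIGHPASS_HZ >= rate / 2:
        raise ConfigurationError(
            f"high-pass cutoff {HIGHPASS_HZ} Hz is not below the "
            f"Nyquist frequency of a {rate} Hz recording")
    return sps.butter(HIGHPASS_ORDER, HIGHPASS_HZ,
                      btype="highpass", fs=rate, output="sos")


def _filt(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return sps.sosfiltfilt(sos, x)
    # initialize the causal filter at its step steady state so the DC
    # level present at switch-on does not bleed into the first epochs
    zi = sps.sosfilt_zi(sos) * x[0]
    out, _ = sps.sosfilt(sos, x, zi=zi)
    return out


def preprocess(rec: TriaxialRecording, scheme: str,
               zero_phase: bool = False) -> PreprocessedSignal:
    """Apply one preprocessing scheme to a regularized recording."""
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown preprocessing scheme {scheme!r}")
    rate = rec.nominal_rate
    if scheme in ("UFX", "UFY", "UFZ"):
        values = {"UFX": rec.x, "UFY": rec.y, "UFZ": rec.z}[scheme].copy()
    elif scheme in ("UFM", "UFNM", "ENMO"):
        ufm = np.sqrt(rec.x**2 + rec.y**2 + rec.z**2)
        if scheme == "UFM":
            values = ufm
        elif scheme == "UFNM":
            values = np.abs(ufm - 1.0)
        else:
            values = np.maximum(ufm - 1.0, 0.0)
    elif scheme in ("FX", "FY", "FZ"):
        sos = bandpass_sos(rate)
        axis = {"FX": rec.x, "FY": rec.y, "FZ": rec.z}[scheme]
        values = _filt(sos, axis, zero_phase)
    elif scheme == "FMpre":
        sos = bandpass_sos(rate)
        fx = _filt(sos, rec.x, zero_phase)
        fy = _filt(sos, rec.y, zero_phase)
        fz = _filt(sos, rec.z, zero_phase)
        values = np.sqrt(fx**2 + fy**2 + fz**2)
    elif scheme == "FMpost":
        sos = bandpass_sos(rate)
        ufm = np.sqrt(rec.x**2 + rec.y**2 + rec.z**2)
        values = _filt(sos, ufm, zero_phase)
    elif scheme == "HFMpre":
        sos = highpass_sos(rate)
        hx = _filt(sos, rec.x, zero_phase)
        hy = _filt(sos, rec.y, zero_phase)
        hz = _filt(sos, rec.z, zero_phase)
        values = np.sqrt(hx**2 + hy**2 + hz**2)
    else:  # pragma: no cover
        raise ConfigurationError(scheme)
    return PreprocessedSignal(scheme=scheme, values=values,
                              timestamps=rec.timestamps, rate=rate)


#: Schemes that may take negative values and therefore need
#: rectification before mean-based (circadian) analyses.
RECTIFIABLE = frozenset({"FX", "FY", "FZ", "FMpost"})


def rectify(sig: PreprocessedSignal) -> PreprocessedSignal:
    """Absolute value of a signed filtered signal (FX/FY/FZ/FMpost).

    Calling it on any other scheme is an error: nonnegative schemes must
    not be silently double-processed.
    """
    if sig.scheme not in RECTIFIABLE:
        raise ConfigurationError(
            f"rectify is only defined for {sorted(RECTIFIABLE)}, "
            f"not {sig.scheme!r}")
    return PreprocessedSignal(scheme=sig.scheme,
                              values=np.abs(sig.values),
                              timestamps=sig.timestamps,
                              rate=sig.rate, rectified=True)


def axis_bundle(rec: TriaxialRecording, filtered: bool,
                zero_phase: bool = False) -> AxisBundle:
    """Triaxial bundle (UFXYZ raw, or FXYZ band-pass filtered) for the
    Activity Index metric."""
    if filtered:
        sos = bandpass_sos(rec.nominal_rate)
        x = _filt(sos, rec.x, zero_phase)
        y = _filt(sos, rec.y, zero_phase)
        z = _filt(sos, rec.z, zero_phase)
        return AxisBundle("FXYZ", x, y, z, rec.timestamps, rec.nominal_rate)
    return AxisBundle("UFXYZ", rec.x.copy(), rec.y.copy(), rec.z.copy(),
                      rec.timestamps, rec.nominal_rate)
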