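"""Core containers and exceptions shared across the pipeline.

All acceleration values are expressed in units of g (standard gravity,
fixed at exactly 1 in these units); timestamps are integer milliseconds
since the Unix epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ActipipeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ActipipeError, ValueError):
    """Invalid configuration or parameter combination."""


class FormatError(ActipipeError, ValueError):
    """Malformed input file or container."""


class UndefinedValueError(ActipipeError, ValueError):
    """A quantity is mathematically undefined for the given input
    (e.g. a zero denominator in a ratio indicator)."""


#: Preprocessing schemes for single-channel acceleration signals.
SCHEMES = (
    "UFX", "UFY", "UFZ",          # raw per-axis
    "UFM", "UFNM", "ENMO",        # unfiltered magnitude and gravity-removed
    "FX", "FY", "FZ",             # band-pass filtered per-axis
    "FMpre", "FMpost", "HFMpre",  # filtered magnitudes
)

#: Schemes whose values still carry the static gravity component.
GRAVITY_SCHEMES = frozenset({"UFX", "UFY", "UFZ", "UFM"})

#: Preprocessing family of each scheme (the grouping that drives the
#: clustering of methods: whether/where digital filtering was applied).
SCHEME_FAMILY = {
    "UFX": "raw-axis", "UFY": "raw-axis", "UFZ": "raw-axis",
    "UFXYZ": "raw-axis",
    "UFM": "unfiltered-magnitude", "UFNM": "unfiltered-magnitude",
    "ENMO": "unfiltered-magnitude",
    "FX": "filtered-axis", "FY": "filtered-axis", "FZ": "filtered-axis",
    "FXYZ": "filtered-axis-magnitude", "FMpre": "filtered-axis-magnitude",
    "HFMpre": "filtered-axis-magnitude",
    "FMpost": "filtered-magnitude",
}


def _as_float_array(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=np.float64)
    if arr.ndim != 1:
        raise FormatError(f"{name} must be one-dimensional")
    return arr


@dataclass
class TriaxialRecording:
    """Raw triaxial wrist acceleration.

    Attributes
    ----------
    subject_id : str
        Identifier of the recorded subject.
    timestamps : ndarray of int64
        Sample times in milliseconds since the epoch, nondecreasing.
    x, y, z : ndarray of float64
        Per-axis acceleration in g units.
    nominal_rate : float
        Nominal sampling rate in samples/second.
    """

    subject_id: str
    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    nominal_rate: float = 10.0

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.x = _as_float_array(self.x, "x")
        self.y = _as_float_array(self.y, "y")
        self.z = _as_float_array(self.z, "z")
        n = len(self.timestamps)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise FormatError("timestamps and axis arrays must share one length")
        if n and np.any(np.diff(self.timestamps) < 0):
            raise FormatError("timestamps must be nondecreasing")
        for name, arr in (("x", self.x), ("y", self.y), ("z", self.z)):
            if n and not np.all(np.isfinite(arr)):
                raise FormatError(f"non-finite values in axis {name}")
        if self.nominal_rate <= 0:
            raise ConfigurationError("nominal_rate must be positive")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) view of the three axes."""
        return np.column_stack([self.x, self.y, self.z])

    def is_regular(self) -> bool:
        """True when consecutive timestamps sit on the exact
        1000/nominal_rate ms grid."""
        if len(self) < 2:
            return True
        step = 1000.0 / self.nominal_rate
        expect = self.timestamps[0] + np.round(
            np.arange(len(self)) * step).astype(np.int64)
        return bool(np.array_equal(self.timestamps, expect))


@dataclass
class PreprocessedSignal:
    """Single-channel acceleration series labeled by preprocessing scheme."""

    scheme: str
    values: np.ndarray
    timestamps: np.ndarray
    rate: float
    rectified: bool = False

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ConfigurationError(f"unknown preprocessing scheme {self.scheme!r}")
        self.values = _as_float_array(self.values, "values")
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        if len(self.values) != len(self.timestamps):
            raise FormatError("values and timestamps must share one length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def gravity_present(self) -> bool:
        return self.scheme in GRAVITY_SCHEMES

    @property
    def label(self) -> str:
        return f"|{self.scheme}|" if self.rectified else self.scheme


@dataclass
class AxisBundle:
    """Triaxial bundle of (optionally filtered) per-axis signals; the
    input the Activity Index metric operates on."""

    scheme: str  # "UFXYZ" or "FXYZ"
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    timestamps: np.ndarray
    rate: float

    def __post_init__(self):
        if self.scheme not in ("UFXYZ", "FXYZ"):
            raise ConfigurationError("AxisBundle scheme must be UFXYZ or FXYZ")
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class ActivitySeries:
    """Epoch-level activity values produced by one determination method.

    ``method`` has the form METRIC(SCHEME) for generalized methods
    (e.g. ``"PIM(FMpre)"``) or a device name (``"AC"``, ``"MW"``).
    """

    method: str
    epoch_length: int
    epoch_starts: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.epoch_starts = np.asarray(self.epoch_starts, dtype=np.int64)
        self.values = _as_float_array(self.values, "values")
        if len(self.values) != len(self.epoch_starts):
            raise FormatError("values and epoch_starts must share one length")
        if len(self.epoch_starts) > 1:
            step = self.epoch_length * 1000
            if np.any(np.diff(self.epoch_starts) != step):
                raise FormatError("epochs must be contiguous and non-overlapping")
        if len(self.values) and np.min(self.values) < 0:
            raise FormatError("activity values must be nonnegative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CalibrationReport:
    """Result of the sphere-fit auto-calibration."""

    offsets: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scales: np.ndarray = field(default_factory=lambda: np.ones(3))
    residual: float = 0.0          # RMS deviation of still-point norms from 1 g
    n_still: int = 0
    calibrated: bool = False       # False => insufficient still data, no-op
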