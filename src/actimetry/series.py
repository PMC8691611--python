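"""Domain containers: recordings, preprocessed datasets, activity series.

All acceleration values are in units of g throughout the package.  A raw
recording holds the three axial samples plus acquisition parameters; each
preprocessing step yields a :class:`DatasetSeries` tagged with its kind in
the dataset taxonomy (UFX..FMpost, plus the specially conditioned HFEN_M);
each metric application yields an :class:`ActivitySeries` with one value per
epoch and full provenance (metric, source dataset, epoch length, threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import AlignmentError, ParameterError, RangeError, SizeError

#: Single-series dataset kinds produced by preprocessing.
DATASET_KINDS = (
    "UFX", "UFY", "UFZ", "UFM", "UFNM",
    "FX", "FY", "FZ", "FMpre", "FMpost", "HFEN_M",
)

#: Kinds that are magnitudes / absolute values and must be >= 0 everywhere.
NONNEGATIVE_KINDS = frozenset({"UFM", "UFNM", "FMpre", "HFEN_M"})

#: Axial triples addressed collectively (inputs of the Activity Index).
TRIAXIAL_KINDS = ("UFXYZ", "FXYZ")

METRIC_IDS = ("PIMr", "PIMs", "ZCM", "TAT", "MAD", "ENMO", "HFEN", "AI")

COMBINATION_METHODS = ("none", "sum", "sum_sq", "vm3",
                       "axis_x", "axis_y", "axis_z")


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1:
        raise ParameterError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class RawRecording:
    """Uniformly sampled triaxial acceleration in g.

    Parameters
    ----------
    x, y, z : array-like
        Per-axis acceleration samples in g; equal lengths, length >= 1.
    sampling_interval : float
        T_s in seconds (e.g. 0.1 for 10 Hz).
    range_g : float
        Sensor full scale; samples must lie within [-range_g, +range_g].
    start_time : str, optional
        Opaque timestamp label carried through outputs.
    subject_id : str, optional
        Opaque subject label.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sampling_interval: float
    range_g: float = 8.0
    start_time: Optional[str] = None
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.x = _as_float_array(self.x, "x")
        self.y = _as_float_array(self.y, "y")
        self.z = _as_float_array(self.z, "z")
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise AlignmentError(
                f"axes must have equal length, got "
                f"{len(self.x)}/{len(self.y)}/{len(self.z)}")
        if len(self.x) < 1:
            raise SizeError("recording must contain at least one sample")
        if not self.sampling_interval > 0:
            raise ParameterError("sampling_interval must be positive")
        if not self.range_g > 0:
            raise ParameterError("range_g must be positive")
        for name, axis in (("x", self.x), ("y", self.y), ("z", self.z)):
            bad = np.abs(axis) > self.range_g
            if bad.any():
                i = int(np.argmax(bad))
                raise RangeError(
                    f"axis {name} sample {i} = {axis[i]:g} g outside "
                    f"+/-{self.range_g:g} g")

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.sampling_interval

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.sampling_interval

    def as_array(self) -> np.ndarray:
        """Samples as an (n, 3) array with columns x, y, z."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class FilterSpec:
    """Butterworth filter specification.

    Defaults reproduce the band-pass common to actigraph hardware:
    f_L = 0.25 Hz, f_H = 2.5 Hz, order 3, applied causally (single pass).
    ``mode='zero_phase'`` selects forward-backward filtering, which doubles
    the effective order and removes phase distortion.
    """

    kind: str = "bandpass"
    low_cut_hz: float = 0.25
    high_cut_hz: Optional[float] = 2.5
    order: int = 3
    mode: str = "causal"

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "highpass"):
            raise ParameterError(f"unknown filter kind {self.kind!r}")
        if self.mode not in ("causal", "zero_phase"):
            raise ParameterError(f"unknown filter mode {self.mode!r}")
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")
        if not self.low_cut_hz > 0:
            raise ParameterError("low cutoff must be positive")
        if self.kind == "bandpass":
            if self.high_cut_hz is None:
                raise ParameterError("bandpass filter needs a high cutoff")
            if not self.low_cut_hz < self.high_cut_hz:
                raise ParameterError("need low_cut_hz < high_cut_hz")

    def validate_for_fs(self, fs: float) -> None:
        nyq = fs / 2.0
        top = self.high_cut_hz if self.kind == "bandpass" else self.low_cut_hz
        if top >= nyq:
            raise ParameterError(
                f"cutoff {top:g} Hz not below Nyquist {nyq:g} Hz")


#: The band-pass the comparison framework uses by default.
DEFAULT_BANDPASS = FilterSpec()

#: The high-pass that conditions axial data for the HFEN metric.
HFEN_HIGHPASS = FilterSpec(kind="highpass", low_cut_hz=0.2,
                           high_cut_hz=None, order=4)


@dataclass
class DatasetSeries:
    """One preprocessed 1-D series tagged with its taxonomy kind."""

    kind: str
    values: np.ndarray
    sampling_interval: float
    lineage: str = ""

    def __post_init__(self) -> None:
        if self.kind not in DATASET_KINDS:
            raise ParameterError(f"unknown dataset kind {self.kind!r}")
        self.values = _as_float_array(self.values, "values")
        if not self.sampling_interval > 0:
            raise ParameterError("sampling_interval must be positive")
        if self.kind in NONNEGATIVE_KINDS and np.any(self.values < 0):
            raise ParameterError(
                f"{self.kind} is a magnitude dataset and must be >= 0")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class EpochParams:
    """Epoch grid: non-overlapping windows of T_e seconds (default 60)."""

    epoch_length_s: float = 60.0

    def __post_init__(self) -> None:
        if not self.epoch_length_s > 0:
            raise ParameterError("epoch length must be positive")

    def samples_per_epoch(self, sampling_interval: float) -> int:
        """n = T_e / T_s; T_e must be an integer multiple of T_s, n >= 2."""
        ratio = self.epoch_length_s / sampling_interval
        n = int(round(ratio))
        if abs(ratio - n) > 1e-6 * max(1.0, n):
            raise ParameterError(
                f"epoch length {self.epoch_length_s} s is not an integer "
                f"multiple of the sampling interval {sampling_interval} s")
        if n < 2:
            raise ParameterError("need at least 2 samples per epoch")
        return n


@dataclass
class ThresholdSpec:
    """Level-crossing threshold with provenance.

    ``base_offset`` is 1 g exactly for the UFM dataset, whose values sit on
    top of the constant gravity component; for every other dataset the
    threshold is referenced to 0 g.
    """

    value: float
    mode: str = "fixed"
    base_offset: float = 0.0
    source_kind: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "sd_adaptive", "sweep"):
            raise ParameterError(f"unknown threshold mode {self.mode!r}")
        if not np.isfinite(self.value):
            raise ParameterError("threshold value must be finite")
        if self.value < self.base_offset - 1e-12:
            raise ParameterError(
                f"threshold {self.value:g} below base offset "
                f"{self.base_offset:g}")
        if self.source_kind is not None:
            expected = 1.0 if self.source_kind == "UFM" else 0.0
            if self.base_offset != expected:
                raise ParameterError(
                    f"base_offset must be {expected:g} g for dataset "
                    f"{self.source_kind}")


@dataclass
class NoiseModel:
    """Systematic (still-device) noise variance in g^2."""

    variance: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ParameterError("noise variance must be >= 0")


@dataclass
class ActivitySeries:
    """Epoch-sampled activity values with full provenance."""

    values: np.ndarray
    metric_id: str
    dataset_kind: str
    epoch: EpochParams = field(default_factory=EpochParams)
    threshold: Optional[ThresholdSpec] = None
    combination: str = "none"
    params: dict = field(default_factory=dict)
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "values")
        if self.metric_id not in METRIC_IDS:
            raise ParameterError(f"unknown metric id {self.metric_id!r}")
        if self.combination not in COMBINATION_METHODS:
            raise ParameterError(f"unknown combination {self.combination!r}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def label(self) -> str:
        """Readable identifier, e.g. ``ZCM(UFM)`` or ``vm3[TAT](FXYZ)``."""
        if self.combination in ("none", "axis_x", "axis_y", "axis_z"):
            return f"{self.metric_id}({self.dataset_kind})"
        return f"{self.combination}[{self.metric_id}]({self.dataset_kind})"
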