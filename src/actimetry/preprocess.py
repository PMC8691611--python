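"""Preprocessing: filtering, magnitudes, and the dataset taxonomy.

From one raw triaxial recording six dataset types can be derived:

* **UFXYZ** (UFX, UFY, UFZ) — raw axial accelerations, unmodified;
* **UFM** — Euclidean magnitude of the raw axial signals (carries the
  constant 1 g gravity component);
* **UFNM** — gravity-normalized magnitude, ``|UFM - 1 g|``;
* **FXYZ** (FX, FY, FZ) — axial signals band-pass filtered (Butterworth,
  0.25–2.5 Hz, order 3 by default);
* **FMpre** — magnitude of the *filtered* axial signals;
* **FMpost** — the band-pass filter applied to the UFM magnitude.

FMpre and FMpost differ because the nonlinear magnitude operation does not
commute with linear filtering.  A separately conditioned **HFEN_M** series
(per-axis 4th-order 0.2 Hz high-pass, then magnitude) feeds the HFEN metric.

Filters run causally (single pass) by default, mimicking on-device hardware;
``mode='zero_phase'`` selects forward-backward filtering.  Designs use
cascaded second-order sections, so high orders (e.g. the order-30 variant)
remain numerically stable.  The causal filter state is initialized to the
steady-state response for the first sample, avoiding an artificial onset
transient proportional to the signal's DC level.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import AlignmentError, SizeError
from .series import (DEFAULT_BANDPASS, HFEN_HIGHPASS, DatasetSeries,
                     FilterSpec, RawRecording)


def design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Second-order-section coefficients for a filter spec at rate fs."""
    spec.validate_for_fs(fs)
    if spec.kind == "bandpass":
        wn = [spec.low_cut_hz, spec.high_cut_hz]
        btype = "bandpass"
    else:
        wn = spec.low_cut_hz
        btype = "highpass"
    return sps.butter(spec.order, wn, btype=btype, fs=fs, output="sos")


def butterworth_filter(series: np.ndarray, spec: FilterSpec,
                       fs: float) -> np.ndarray:
    """Apply a Butterworth filter to a 1-D series.

    Causal mode runs a single forward pass with the internal state
    initialized to the steady state for ``series[0]``; zero-phase mode uses
    forward-backward filtering (doubling the effective order).
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise AlignmentError("butterworth_filter expects a 1-D series")
    if len(x) <= 3 * spec.order:
        raise SizeError(
            f"series of length {len(x)} too short for order {spec.order}")
    sos = design_sos(spec, fs)
    if spec.mode == "zero_phase":
        return sps.sosfiltfilt(sos, x)
    zi = sps.sosfilt_zi(sos) * x[0]
    y, _ = sps.sosfilt(sos, x, zi=zi)
    return y


def magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm of three aligned axial series."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    if not (x.shape == y.shape == z.shape):
        raise AlignmentError(
            f"axes must share shape, got {x.shape}/{y.shape}/{z.shape}")
    return np.sqrt(x * x + y * y + z * z)


def normalize_ufnm(ufm: np.ndarray) -> np.ndarray:
    """Gravity-normalized magnitude ``|r - 1 g|`` (UFM values in g)."""
    return np.abs(np.asarray(ufm, dtype=np.float64) - 1.0)


def hfen_magnitude(rec: RawRecording,
                   spec: FilterSpec = HFEN_HIGHPASS) -> DatasetSeries:
    """Specially conditioned magnitude for the HFEN metric.

    Each axis is high-pass filtered (default: 4th-order Butterworth,
    0.2 Hz cut-off) before the magnitude is taken, so gravity is removed
    ahead of the norm.
    """
    fs = rec.fs
    fx = butterworth_filter(rec.x, spec, fs)
    fy = butterworth_filter(rec.y, spec, fs)
    fz = butterworth_filter(rec.z, spec, fs)
    return DatasetSeries(
        kind="HFEN_M", values=magnitude(fx, fy, fz),
        sampling_interval=rec.sampling_interval,
        lineage=(f"per-axis highpass {spec.low_cut_hz:g} Hz order "
                 f"{spec.order} ({spec.mode}), then magnitude"))


def build_datasets(rec: RawRecording,
                   spec: Optional[FilterSpec] = None,
                   *, include_hfen: bool = False,
                   hfen_spec: FilterSpec = HFEN_HIGHPASS,
                   ) -> Dict[str, DatasetSeries]:
    """Derive the dataset taxonomy from a raw recording.

    Returns the ten single-series kinds {UFX, UFY, UFZ, UFM, UFNM, FX, FY,
    FZ, FMpre, FMpost} (the six taxonomy types with axial types expanded);
    ``include_hfen=True`` adds the HFEN_M series.
    """
    spec = spec if spec is not None else DEFAULT_BANDPASS
    fs = rec.fs
    ts = rec.sampling_interval
    band = (f"bandpass {spec.low_cut_hz:g}-{spec.high_cut_hz:g} Hz order "
            f"{spec.order} ({spec.mode})")

    out: Dict[str, DatasetSeries] = {}
    for name, axis in (("UFX", rec.x), ("UFY", rec.y), ("UFZ", rec.z)):
        out[name] = DatasetSeries(kind=name, values=axis.copy(),
                                  sampling_interval=ts, lineage="raw axial")
    ufm = magnitude(rec.x, rec.y, rec.z)
    out["UFM"] = DatasetSeries(kind="UFM", values=ufm, sampling_interval=ts,
                               lineage="magnitude of raw axials")
    out["UFNM"] = DatasetSeries(kind="UFNM", values=normalize_ufnm(ufm),
                                sampling_interval=ts,
                                lineage="|UFM - 1 g|")
    fx = butterworth_filter(rec.x, spec, fs)
    fy = butterworth_filter(rec.y, spec, fs)
    fz = butterworth_filter(rec.z, spec, fs)
    for name, vals in (("FX", fx), ("FY", fy), ("FZ", fz)):
        out[name] = DatasetSeries(kind=name, values=vals,
                                  sampling_interval=ts,
                                  lineage=f"axial, {band}")
    out["FMpre"] = DatasetSeries(kind="FMpre", values=magnitude(fx, fy, fz),
                                 sampling_interval=ts,
                                 lineage=f"magnitude of axials after {band}")
    out["FMpost"] = DatasetSeries(
        kind="FMpost", values=butterworth_filter(ufm, spec, fs),
        sampling_interval=ts, lineage=f"UFM then {band}")
    if include_hfen:
        out["HFEN_M"] = hfen_magnitude(rec, hfen_spec)
    return out


class BandpassFilter(TransformerMixin, BaseEstimator):
    """Butterworth filter as a scikit-learn column transformer.

    Filters each column of X (shape ``(n_samples, n_axes)``) independently.
    ``fit`` designs the second-order sections for the configured rate and
    stores them as ``sos_``.

    Parameters
    ----------
    fs : float
        Sampling rate of the incoming columns in Hz.
    kind, low_cut_hz, high_cut_hz, order, mode :
        See :class:`~actimetry.series.FilterSpec`.
    """

    def __init__(self, fs: float = 10.0, kind: str = "bandpass",
                 low_cut_hz: float = 0.25, high_cut_hz: float = 2.5,
                 order: int = 3, mode: str = "causal"):
        self.fs = fs
        self.kind = kind
        self.low_cut_hz = low_cut_hz
        self.high_cut_hz = high_cut_hz
        self.order = order
        self.mode = mode

    def _spec(self) -> FilterSpec:
        return FilterSpec(kind=self.kind, low_cut_hz=self.low_cut_hz,
                          high_cut_hz=(self.high_cut_hz
                                       if self.kind == "bandpass" else None),
                          order=self.order, mode=self.mode)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        spec = self._spec()
        self.sos_ = design_sos(spec, self.fs)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "sos_")
        X = np.asarray(X, dtype=np.float64)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        spec = self._spec()
        cols = [butterworth_filter(X[:, j], spec, self.fs)
                for j in range(X.shape[1])]
        out = np.column_stack(cols)
        return out[:, 0] if squeeze else out
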