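"""Reading and writing recordings and activity series.

Two recording formats are supported:

* CSV with 3 numeric columns (x, y, z) or 4 (t, x, y, z), optional header
  row; values in g (a ``scale`` override converts raw counts).  With four
  columns the time column is used only to validate uniform sampling.
* A self-contained binary container: little-endian header
  ``magic b'ACTG' | version uint16 | fs float64 | range_g float64 |
  n uint64`` followed by n interleaved (x, y, z) float32 triples in g.

Activity series are written as CSV with ``#``-prefixed metadata header rows
(metric id, dataset kind, epoch length, threshold if any) and one
(epoch_index, value) row per epoch.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParameterError, SamplingError, SizeError
from .series import ActivitySeries, EpochParams, RawRecording, ThresholdSpec

_MAGIC = b"ACTG"
_VERSION = 1
_HEADER = struct.Struct("<4sHddQ")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    if path.suffix.lower() in (".bin", ".actg"):
        return "binary"
    return "csv"


def read_recording(path, format: Optional[str] = None, *,
                   fs: Optional[float] = None, range_g: float = 8.0,
                   scale: float = 1.0,
                   subject_id: Optional[str] = None) -> RawRecording:
    """Read a raw triaxial recording from CSV or the binary container.

    Parameters
    ----------
    fs : float, optional
        Sampling rate override.  Required for 3-column CSV; for 4-column
        CSV it defaults to the rate inferred from the time column.
    scale : float
        Multiplied into every sample (converts raw counts to g).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "binary":
        return _read_binary(path, scale=scale, subject_id=subject_id)
    if fmt != "csv":
        raise ParameterError(f"unknown format {fmt!r}")
    return _read_csv(path, fs=fs, range_g=range_g, scale=scale,
                     subject_id=subject_id)


def _read_csv(path: Path, *, fs, range_g, scale, subject_id) -> RawRecording:
    try:
        first = pd.read_csv(path, header=None, nrows=1)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    has_header = not all(
        np.issubdtype(np.asarray([v]).dtype, np.number) or _is_number(v)
        for v in first.iloc[0])
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] not in (3, 4):
        raise FormatError(
            f"{path}: expected 3 or 4 columns, found {df.shape[1]}")
    try:
        data = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric data: {exc}") from exc
    if df.shape[1] == 4:
        t, xyz = data[:, 0], data[:, 1:]
        if len(t) >= 2:
            dt = np.diff(t)
            ts = float(np.median(dt))
            if ts <= 0:
                raise SamplingError(f"{path}: non-increasing timestamps")
            if np.any(np.abs(dt - ts) > 0.01 * ts):
                raise SamplingError(
                    f"{path}: timestamps deviate from uniform sampling by "
                    f"more than 1% of T_s={ts:g} s")
        else:
            ts = None
        if fs is None:
            if ts is None:
                raise ParameterError("fs required for a single-row file")
            fs = 1.0 / ts
    else:
        xyz = data
        if fs is None:
            raise ParameterError("fs is required for 3-column CSV input")
    xyz = xyz * scale
    return RawRecording(xyz[:, 0], xyz[:, 1], xyz[:, 2],
                        sampling_interval=1.0 / fs, range_g=range_g,
                        subject_id=subject_id)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_recording(rec: RawRecording, path, format: Optional[str] = None,
                    *, include_time: bool = False) -> None:
    """Write a recording as CSV (default) or the binary container."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "binary":
        _write_binary(rec, path)
        return
    cols = {"x": rec.x, "y": rec.y, "z": rec.z}
    if include_time:
        t = np.arange(rec.n_samples) * rec.sampling_interval
        cols = {"t": t, **cols}
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


def _write_binary(rec: RawRecording, path: Path) -> None:
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(_MAGIC, _VERSION, rec.fs, rec.range_g,
                              rec.n_samples))
        interleaved = rec.as_array().astype("<f4")
        fh.write(interleaved.tobytes())


def _read_binary(path: Path, *, scale, subject_id) -> RawRecording:
    raw = path.read_bytes()
    if len(raw) < _HEADER.size:
        raise FormatError(f"{path}: truncated header")
    magic, version, fs, range_g, n = _HEADER.unpack_from(raw)
    if magic != _MAGIC:
        raise FormatError(f"{path}: bad magic {magic!r}")
    if version != _VERSION:
        raise FormatError(f"{path}: unsupported container version {version}")
    expected = _HEADER.size + 12 * n
    if len(raw) != expected:
        raise FormatError(
            f"{path}: payload size {len(raw) - _HEADER.size} does not match "
            f"header n={n}")
    xyz = np.frombuffer(raw, dtype="<f4", offset=_HEADER.size)
    xyz = xyz.reshape(n, 3).astype(np.float64) * scale
    return RawRecording(xyz[:, 0], xyz[:, 1], xyz[:, 2],
                        sampling_interval=1.0 / fs, range_g=range_g,
                        subject_id=subject_id)


# -- activity series ---------------------------------------------------------

def write_activity(series: ActivitySeries, path) -> None:
    """Write an activity series as CSV with metadata header rows."""
    if len(series) == 0:
        raise SizeError("refusing to write an empty activity series")
    path = Path(path)
    lines = [
        f"# metric: {series.metric_id}",
        f"# dataset: {series.dataset_kind}",
        f"# epoch_length_s: {series.epoch.epoch_length_s:g}",
        f"# combination: {series.combination}",
    ]
    if series.subject_id is not None:
        lines.append(f"# subject: {series.subject_id}")
    if series.threshold is not None:
        thr = series.threshold
        lines.append(f"# threshold_g: {float(thr.value)!r}")
        lines.append(f"# threshold_mode: {thr.mode}")
        lines.append(f"# threshold_base_offset_g: {thr.base_offset:g}")
    for key, val in sorted(series.params.items()):
        lines.append(f"# param_{key}: {val}")
    lines.append("epoch,value")
    for i, v in enumerate(series.values):
        lines.append(f"{i},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_activity(path) -> ActivitySeries:
    """Read an activity series written by :func:`write_activity`."""
    path = Path(path)
    meta: dict = {}
    rows: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif line.startswith("epoch"):
                continue
            else:
                _, _, val = line.partition(",")
                rows.append(float(val))
    if "metric" not in meta or "dataset" not in meta:
        raise FormatError(f"{path}: missing metadata header rows")
    threshold = None
    if "threshold_g" in meta:
        from .series import DATASET_KINDS
        threshold = ThresholdSpec(
            value=float(meta["threshold_g"]),
            mode=meta.get("threshold_mode", "fixed"),
            base_offset=float(meta.get("threshold_base_offset_g", 0.0)),
            source_kind=(meta["dataset"]
                         if meta["dataset"] in DATASET_KINDS else None))
    params = {k[len("param_"):]: v for k, v in meta.items()
              if k.startswith("param_")}
    return ActivitySeries(
        values=np.asarray(rows, dtype=np.float64),
        metric_id=meta["metric"],
        dataset_kind=meta["dataset"],
        epoch=EpochParams(float(meta.get("epoch_length_s", 60.0))),
        threshold=threshold,
        combination=meta.get("combination", "none"),
        params=params,
        subject_id=meta.get("subject"))
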