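"""Correlation machinery for comparing activity-signal definitions.

A :class:`SignalCatalog` enumerates fully specified activity-signal
definitions (metric x dataset x combination x threshold mode); for each
subject every entry is computed on the same epoch grid, pairwise Pearson
coefficients are taken (in the time domain directly on the activity values,
in the frequency domain on Welch power-spectral-density estimates), and the
per-subject matrices are reduced to a single mean +/- SD matrix by
averaging identically located cells across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps
from scipy import stats

from .axial import combine_axial
from .exceptions import (AlignmentError, CoverageError, ParameterError,
                         SizeError, UndefinedCorrelationError)
from .metrics import (check_applicability, compute_activity,
                      estimate_noise_variance, LEVEL_CROSSING_METRICS)
from .preprocess import build_datasets
from .series import (ActivitySeries, EpochParams, FilterSpec, RawRecording)
from .thresholds import sd_threshold


def _values(a) -> np.ndarray:
    return a.values if isinstance(a, ActivitySeries) else \
        np.asarray(a, dtype=np.float64)


def pearson(a, b) -> float:
    """Product-moment correlation between two aligned activity signals."""
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise AlignmentError(
            f"signals must share the epoch grid, got {va.shape}/{vb.shape}")
    if np.std(va) == 0.0 or np.std(vb) == 0.0:
        raise UndefinedCorrelationError(
            "Pearson correlation undefined for a constant signal")
    return float(stats.pearsonr(va, vb).statistic)


@dataclass
class PsdParams:
    """Welch PSD settings used for frequency-domain comparison."""

    segment_epochs: int = 256
    overlap: float = 0.5
    window: str = "hann"
    detrend: str = "linear"


def power_spectrum(a, psd: Optional[PsdParams] = None) -> np.ndarray:
    """One-sided Welch PSD of an activity signal (unit epoch rate)."""
    psd = psd if psd is not None else PsdParams()
    v = _values(a)
    if len(v) < 4 * psd.segment_epochs:
        raise SizeError(
            f"need at least {4 * psd.segment_epochs} epochs for PSD with "
            f"segment length {psd.segment_epochs}, got {len(v)}")
    _, p = sps.welch(v, fs=1.0, window=psd.window,
                     nperseg=psd.segment_epochs,
                     noverlap=int(psd.overlap * psd.segment_epochs),
                     detrend=psd.detrend)
    return p


def spectral_correlation(a, b, psd: Optional[PsdParams] = None) -> float:
    """Pearson coefficient between the PSD estimates of two signals."""
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise AlignmentError("signals must share the epoch grid")
    return pearson(power_spectrum(va, psd), power_spectrum(vb, psd))


# -- signal catalog ----------------------------------------------------------

@dataclass(frozen=True)
class SignalSpec:
    """One fully specified activity-signal definition."""

    metric: str
    dataset: str
    combination: str = "none"
    threshold_mode: str = "sd"  # "sd" or a fixed level serialized as float

    @property
    def id(self) -> str:
        if self.combination == "none":
            return f"{self.metric}({self.dataset})"
        return f"{self.combination}[{self.metric}]({self.dataset})"

    def validate(self) -> None:
        if self.combination == "none":
            check_applicability(self.metric, self.dataset)
        else:
            if self.dataset not in ("UFXYZ", "FXYZ"):
                raise ParameterError(
                    f"combined entry {self.id} must target an axial triple")
            axes = (("UFX", "UFY", "UFZ") if self.dataset == "UFXYZ"
                    else ("FX", "FY", "FZ"))
            for ax in axes:
                check_applicability(self.metric, ax)


@dataclass
class SignalCatalog:
    """Deterministic, manifest-backed enumeration of signal definitions."""

    entries: List[SignalSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ParameterError(f"duplicate catalog entries: {dupes}")
        for e in self.entries:
            e.validate()

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> List[str]:
        return [e.id for e in self.entries]

    def to_manifest(self, path) -> None:
        payload = [{"metric": e.metric, "dataset": e.dataset,
                    "combination": e.combination,
                    "threshold_mode": e.threshold_mode}
                   for e in self.entries]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_manifest(cls, path) -> "SignalCatalog":
        payload = yaml.safe_load(Path(path).read_text())
        entries = [SignalSpec(metric=d["metric"], dataset=d["dataset"],
                              combination=d.get("combination", "none"),
                              threshold_mode=d.get("threshold_mode", "sd"))
                   for d in payload]
        return cls(entries=entries)


_MAGNITUDE_SETS = ("UFM", "UFNM", "FMpre", "FMpost")
_AXIAL_F = ("FX", "FY", "FZ")
_AXIAL_UF = ("UFX", "UFY", "UFZ")


def default_catalog(include_axial: bool = True,
                    include_combinations: bool = True) -> SignalCatalog:
    """Every (metric, dataset, mode) combination the applicability matrix
    permits, plus the three combination indicators for the axial metrics.

    The enumeration is deterministic; write it with
    :meth:`SignalCatalog.to_manifest` to reproduce a run exactly.
    """
    entries: List[SignalSpec] = []
    for ds in _MAGNITUDE_SETS:
        for metric in ("PIMr", "PIMs", "ZCM", "TAT", "MAD"):
            entries.append(SignalSpec(metric, ds))
    entries.append(SignalSpec("ENMO", "UFM"))
    entries.append(SignalSpec("HFEN", "HFEN_M"))
    entries.append(SignalSpec("AI", "UFXYZ"))
    entries.append(SignalSpec("AI", "FXYZ"))
    if include_axial:
        for ax in _AXIAL_F:
            for metric in ("PIMr", "PIMs", "ZCM", "TAT", "MAD"):
                entries.append(SignalSpec(metric, ax))
        for ax in _AXIAL_UF:
            entries.append(SignalSpec("MAD", ax))
    if include_combinations:
        for metric in ("PIMr", "PIMs", "ZCM", "TAT", "MAD"):
            for method in ("sum", "sum_sq", "vm3"):
                entries.append(SignalSpec(metric, "FXYZ", combination=method))
    return SignalCatalog(entries=entries)


def compute_signals(rec: RawRecording,
                    catalog: Optional[SignalCatalog] = None,
                    ep: Optional[EpochParams] = None,
                    filter_spec: Optional[FilterSpec] = None,
                    ) -> Dict[str, ActivitySeries]:
    """Compute every catalog entry for one recording.

    Datasets are derived once; SD-adaptive thresholds are computed per
    dataset (axis-wise for per-axis entries) from the full recording; the
    systematic noise variance for AI comes from the stillest epochs.
    """
    catalog = catalog if catalog is not None else default_catalog()
    ep = ep if ep is not None else EpochParams()
    sets = build_datasets(rec, filter_spec, include_hfen=True)
    noise_cache: list = []  # computed lazily, only if an AI entry exists
    thresholds = {}

    def noise_model():
        if not noise_cache:
            noise_cache.append(estimate_noise_variance(rec, ep))
        return noise_cache[0]

    def thr_for(kind: str, mode: str):
        key = (kind, mode)
        if key not in thresholds:
            if mode == "sd":
                thresholds[key] = sd_threshold(sets[kind])
            else:
                from .series import ThresholdSpec
                thresholds[key] = ThresholdSpec(
                    value=float(mode), mode="fixed",
                    base_offset=1.0 if kind == "UFM" else 0.0,
                    source_kind=kind)
        return thresholds[key]

    def single(metric: str, kind: str, mode: str) -> ActivitySeries:
        thr = (thr_for(kind, mode)
               if metric in LEVEL_CROSSING_METRICS else None)
        return compute_activity(sets[kind], metric, ep, threshold=thr,
                                subject_id=rec.subject_id)

    out: Dict[str, ActivitySeries] = {}
    for e in catalog.entries:
        if e.metric == "AI":
            axes = _AXIAL_UF if e.dataset == "UFXYZ" else _AXIAL_F
            out[e.id] = compute_activity([sets[a] for a in axes], "AI", ep,
                                         noise=noise_model(),
                                         subject_id=rec.subject_id)
        elif e.combination != "none":
            axes = _AXIAL_UF if e.dataset == "UFXYZ" else _AXIAL_F
            per_axis = [single(e.metric, a, e.threshold_mode) for a in axes]
            out[e.id] = combine_axial(*per_axis, method=e.combination)
        else:
            out[e.id] = single(e.metric, e.dataset, e.threshold_mode)
    return out


# -- aggregation across subjects --------------------------------------------

@dataclass
class CorrelationSummary:
    """Mean +/- SD of per-subject Pearson coefficients for one pair."""

    pair: tuple
    mean_r: float
    sd_r: float
    n_subjects: int
    domain: str


@dataclass
class CorrelationMatrixResult:
    """Aggregated correlation matrix with per-cell mean and SD."""

    mean: pd.DataFrame
    sd: pd.DataFrame
    n_subjects: int
    domain: str

    def to_long(self) -> pd.DataFrame:
        ids = list(self.mean.index)
        rows = []
        for i, a in enumerate(ids):
            for b in ids[i:]:
                rows.append({"entry_a": a, "entry_b": b,
                             "domain": self.domain,
                             "mean_r": self.mean.loc[a, b],
                             "sd_r": self.sd.loc[a, b],
                             "n": self.n_subjects})
        return pd.DataFrame(rows)

    def to_csv(self, mean_path, sd_path=None, long_path=None) -> None:
        self.mean.to_csv(mean_path)
        if sd_path is not None:
            self.sd.to_csv(sd_path)
        if long_path is not None:
            self.to_long().to_csv(long_path, index=False)


def _subject_matrix(stack: np.ndarray) -> np.ndarray:
    """Correlation matrix of row signals; constant rows give NaN cells."""
    k = stack.shape[0]
    sd = stack.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(stack)
    c = np.asarray(c, dtype=np.float64).reshape(k, k)
    bad = sd == 0.0
    c[bad, :] = np.nan
    c[:, bad] = np.nan
    np.fill_diagonal(c, np.where(bad, np.nan, 1.0))
    return c


def correlation_matrix(catalog: SignalCatalog,
                       activity_sets: Sequence[Dict[str, ActivitySeries]],
                       domain: str = "time",
                       psd: Optional[PsdParams] = None,
                       ) -> CorrelationMatrixResult:
    """Mean +/- SD correlation matrix across subjects.

    ``activity_sets`` holds one dict (entry id -> ActivitySeries) per
    subject and must cover every catalog entry.  ``domain`` selects direct
    correlation of the activity values (``"time"``) or correlation of their
    Welch PSDs (``"frequency"``).  Cells whose coefficient is undefined for
    some subject (a constant signal) aggregate to NaN — reported missing,
    never coerced to zero.
    """
    if domain not in ("time", "frequency"):
        raise ParameterError(f"unknown domain {domain!r}")
    ids = catalog.ids
    if not activity_sets:
        raise CoverageError("no subjects provided")
    for i, signals in enumerate(activity_sets):
        missing = [sid for sid in ids if sid not in signals]
        if missing:
            raise CoverageError(
                f"subject {i} is missing catalog entries: {missing}")

    mats = []
    for signals in activity_sets:
        if domain == "time":
            stack = np.vstack([signals[sid].values for sid in ids])
        else:
            stack = np.vstack([power_spectrum(signals[sid], psd)
                               for sid in ids])
        mats.append(_subject_matrix(stack))
    cube = np.stack(mats)
    mean = cube.mean(axis=0)
    sd = cube.std(axis=0, ddof=0)
    return CorrelationMatrixResult(
        mean=pd.DataFrame(mean, index=ids, columns=ids),
        sd=pd.DataFrame(sd, index=ids, columns=ids),
        n_subjects=len(activity_sets), domain=domain)
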