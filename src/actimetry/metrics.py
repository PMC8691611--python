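"""The seven epoch-based activity metrics and their applicability rules.

Each metric reduces one epoch (n samples of a preprocessed series, default
60 s) to a single activity value:

* **PIM** — numerical integral of the epoch, either a Riemann sum
  (``T_s * sum(x)``, metric id ``PIMr``) or composite Simpson 3/8 rule
  (``PIMs``).
* **ZCM** — number of times the signal crosses a threshold level.
* **TAT** — total time the signal spends strictly above a threshold.
* **MAD** — mean absolute deviation from the epoch mean.
* **ENMO** — mean of ``max(r - 1 g, 0)``; applicable to UFM only, because
  the metric itself removes gravity.
* **HFEN** — mean of the high-pass-filtered magnitude (HFEN_M input).
* **AI** — per-axis epoch variance averaged after subtracting the
  systematic (still-device) noise variance, floored at zero; operates on
  axial triples (UFXYZ or FXYZ).

Not every metric applies to every dataset kind; :data:`APPLICABILITY`
encodes the permitted pairs and :func:`check_applicability` enforces them.
PIM on signed datasets (FX/FY/FZ/FMpost) integrates absolute values, since
integrating signed accelerations would cancel motion.

Kernels accept a single epoch (1-D) or a stack of epochs (2-D, one epoch
per row) and are vectorized across rows.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (ApplicabilityError, ParameterError, SizeError)
from .series import (ActivitySeries, DatasetSeries, EpochParams, FilterSpec,
                     NoiseModel, RawRecording, ThresholdSpec)

#: Dataset kinds each metric may be applied to.
APPLICABILITY: Dict[str, frozenset] = {
    "PIMr": frozenset({"UFM", "UFNM", "FMpre", "FMpost", "FX", "FY", "FZ"}),
    "PIMs": frozenset({"UFM", "UFNM", "FMpre", "FMpost", "FX", "FY", "FZ"}),
    "ZCM": frozenset({"UFM", "UFNM", "FMpre", "FMpost", "FX", "FY", "FZ"}),
    "TAT": frozenset({"UFM", "UFNM", "FMpre", "FMpost", "FX", "FY", "FZ"}),
    "MAD": frozenset({"UFM", "UFNM", "FMpre", "FMpost", "FX", "FY", "FZ",
                      "UFX", "UFY", "UFZ"}),
    "ENMO": frozenset({"UFM"}),
    "HFEN": frozenset({"HFEN_M"}),
    "AI": frozenset({"UFXYZ", "FXYZ"}),
}

#: Signed dataset kinds on which PIM integrates absolute values.
PIM_RECTIFIED_KINDS = frozenset({"FX", "FY", "FZ", "FMpost"})

LEVEL_CROSSING_METRICS = ("ZCM", "TAT")


def check_applicability(metric_id: str, dataset_kind: str) -> None:
    """Raise :class:`ApplicabilityError` for a disallowed pair."""
    if metric_id not in APPLICABILITY:
        raise ParameterError(f"unknown metric id {metric_id!r}")
    allowed = APPLICABILITY[metric_id]
    if dataset_kind not in allowed:
        raise ApplicabilityError(
            f"{metric_id} is not applicable to the {dataset_kind} dataset; "
            f"permitted datasets: {', '.join(sorted(allowed))}")


def epochs(values: np.ndarray, ep: EpochParams,
           sampling_interval: float) -> np.ndarray:
    """Split a series into consecutive non-overlapping epochs.

    Returns a ``(n_epochs, n)`` view starting at sample 0; a trailing
    remainder shorter than one epoch is dropped.
    """
    x = np.asarray(values, dtype=np.float64)
    n = ep.samples_per_epoch(sampling_interval)
    if len(x) < n:
        raise SizeError(
            f"series of length {len(x)} shorter than one epoch ({n} samples)")
    m = len(x) // n
    return x[:m * n].reshape(m, n)


def _stack(epoch) -> Tuple[np.ndarray, bool]:
    a = np.asarray(epoch, dtype=np.float64)
    if a.ndim == 1:
        return a[None, :], True
    if a.ndim == 2:
        return a, False
    raise ParameterError("epoch input must be 1-D or 2-D")


def _ret(vals: np.ndarray, single: bool):
    return vals[0] if single else vals


def pim(epoch, sampling_interval: float, rule: str = "riemann"):
    """Proportional Integration Method: numerical integral over the epoch.

    ``riemann``: T_s * sum(x).  ``simpson38``: composite Simpson 3/8 rule;
    when (n - 1) is not a multiple of 3 the trailing one or two intervals
    are integrated with the trapezoid rule.
    """
    x, single = _stack(epoch)
    ts = sampling_interval
    if rule == "riemann":
        return _ret(ts * x.sum(axis=1), single)
    if rule != "simpson38":
        raise ParameterError(f"unknown integration rule {rule!r}")
    n = x.shape[1]
    m = ((n - 1) // 3) * 3  # last sample index covered by full 3/8 panels
    total = np.zeros(x.shape[0])
    if m >= 3:
        w = np.full(m + 1, 3.0)
        w[0] = 1.0
        w[m] = 1.0
        w[3:m:3] = 2.0
        total += (3.0 * ts / 8.0) * (x[:, :m + 1] @ w)
    if m < n - 1:
        total += np.trapezoid(x[:, m:], dx=ts, axis=1)
    return _ret(total, single)


def _filled_signs(x: np.ndarray, level: float) -> np.ndarray:
    """Signs of x - level with exact-threshold samples inheriting the side
    of the previous strictly-off-threshold sample (leading ties stay 0)."""
    s = np.sign(x - level)
    if not (s == 0).any():
        return s
    n = s.shape[1]
    idx = np.where(s != 0, np.arange(n)[None, :], 0)
    idx = np.maximum.accumulate(idx, axis=1)
    return np.take_along_axis(s, idx, axis=1)


def zcm(epoch, threshold: Union[ThresholdSpec, float]):
    """Zero Crossing Method: count of threshold-level crossings.

    A crossing is an adjacent pair sitting strictly on opposite sides of
    the level; samples exactly on the level inherit the side of the
    previous off-level sample, so grazing the level does not double-count.
    """
    level = threshold.value if isinstance(threshold, ThresholdSpec) \
        else float(threshold)
    if not np.isfinite(level):
        raise ParameterError("threshold must be finite")
    x, single = _stack(epoch)
    s = _filled_signs(x, level)
    counts = np.count_nonzero(s[:, :-1] * s[:, 1:] < 0, axis=1)
    return _ret(counts.astype(np.float64), single)


def tat(epoch, threshold: Union[ThresholdSpec, float],
        sampling_interval: float):
    """Time Above Threshold in seconds: T_s * #{samples strictly above}."""
    level = threshold.value if isinstance(threshold, ThresholdSpec) \
        else float(threshold)
    if not np.isfinite(level):
        raise ParameterError("threshold must be finite")
    x, single = _stack(epoch)
    return _ret(sampling_interval *
                np.count_nonzero(x > level, axis=1).astype(np.float64),
                single)


def mad(epoch):
    """Mean Amplitude Deviation: mean |r_i - mean(r)| over the epoch."""
    x, single = _stack(epoch)
    return _ret(np.mean(np.abs(x - x.mean(axis=1, keepdims=True)), axis=1),
                single)


def enmo(epoch):
    """Euclidean Norm Minus One: mean of max(r_i - 1 g, 0)."""
    x, single = _stack(epoch)
    return _ret(np.mean(np.maximum(x - 1.0, 0.0), axis=1), single)


def hfen(epoch):
    """High-pass Filtered Euclidean Norm: epoch mean of the HFEN_M input."""
    x, single = _stack(epoch)
    return _ret(x.mean(axis=1), single)


def activity_index(epoch_x, epoch_y, epoch_z,
                   noise: Union[NoiseModel, float],
                   variant: str = "linear"):
    """Activity Index from three aligned axial epochs.

    ``linear``: max((1/3) * sum_m (sigma_m^2 - sigma_bar^2), 0) where
    sigma_m^2 is the per-axis epoch variance and sigma_bar^2 the systematic
    noise variance; ``sqrt`` applies a square root to the floored term.
    """
    nv = noise.variance if isinstance(noise, NoiseModel) else float(noise)
    if nv < 0:
        raise ParameterError("noise variance must be >= 0")
    if variant not in ("linear", "sqrt"):
        raise ParameterError(f"unknown AI variant {variant!r}")
    ax, sx = _stack(epoch_x)
    ay, sy = _stack(epoch_y)
    az, sz = _stack(epoch_z)
    if not (ax.shape == ay.shape == az.shape):
        raise ParameterError("axial epochs must share shape")
    core = sum((a.var(axis=1, ddof=0) - nv) for a in (ax, ay, az)) / 3.0
    core = np.maximum(core, 0.0)
    if variant == "sqrt":
        core = np.sqrt(core)
    return _ret(core, sx and sy and sz)


def estimate_noise_variance(rec: RawRecording,
                            ep: Optional[EpochParams] = None,
                            quantile: float = 0.01) -> NoiseModel:
    """Systematic noise variance from the stillest epochs of a recording.

    Epochs whose summed per-axis variance is at or below the given quantile
    of all epochs are taken as still-device sections; the model variance is
    the mean (over those epochs) of the three-axis variance average.
    """
    ep = ep if ep is not None else EpochParams()
    if not 0 < quantile <= 1:
        raise ParameterError("quantile must be in (0, 1]")
    vx = epochs(rec.x, ep, rec.sampling_interval).var(axis=1, ddof=0)
    vy = epochs(rec.y, ep, rec.sampling_interval).var(axis=1, ddof=0)
    vz = epochs(rec.z, ep, rec.sampling_interval).var(axis=1, ddof=0)
    if len(vx) < 10:
        raise SizeError(
            f"need at least 10 epochs to estimate noise, got {len(vx)}")
    total = vx + vy + vz
    cutoff = np.quantile(total, quantile)
    sel = total <= cutoff
    var = float(np.mean(total[sel]) / 3.0)
    return NoiseModel(variance=var,
                      source=(f"{int(sel.sum())} stillest epochs "
                              f"(quantile {quantile:g} of {len(vx)})"))


AxialTriple = Union[Sequence[DatasetSeries], Dict[str, DatasetSeries]]


def _resolve_triple(data: AxialTriple) -> Tuple[str, Tuple[DatasetSeries,
                                                           DatasetSeries,
                                                           DatasetSeries]]:
    if isinstance(data, dict):
        items = list(data.values())
    else:
        items = list(data)
    if len(items) != 3:
        raise ParameterError("an axial triple needs exactly three series")
    kinds = tuple(s.kind for s in items)
    order: Dict[str, DatasetSeries] = {s.kind: s for s in items}
    if set(kinds) == {"UFX", "UFY", "UFZ"}:
        return "UFXYZ", (order["UFX"], order["UFY"], order["UFZ"])
    if set(kinds) == {"FX", "FY", "FZ"}:
        return "FXYZ", (order["FX"], order["FY"], order["FZ"])
    raise ParameterError(
        f"axial triple must be UFX/UFY/UFZ or FX/FY/FZ, got {kinds}")


def compute_activity(data: Union[DatasetSeries, AxialTriple],
                     metric_id: str,
                     ep: Optional[EpochParams] = None,
                     *,
                     threshold: Optional[Union[ThresholdSpec, float]] = None,
                     noise: Optional[Union[NoiseModel, float]] = None,
                     ai_variant: str = "linear",
                     baseline_subtract: bool = False,
                     subject_id: Optional[str] = None) -> ActivitySeries:
    """Apply a metric per epoch, enforcing the applicability matrix.

    ``data`` is a :class:`DatasetSeries`, or for AI a triple of axial
    series (UFX/UFY/UFZ or FX/FY/FZ).  ZCM/TAT require ``threshold``; AI
    requires ``noise`` (a :class:`NoiseModel` or plain variance in g^2).
    ``baseline_subtract`` removes the stationary 1 g contribution
    (n * T_s per epoch, clipped at zero) from PIM on UFM.
    """
    ep = ep if ep is not None else EpochParams()
    params: dict = {}

    if metric_id == "AI":
        kind, (dx, dy, dz) = _resolve_triple(data)  # also validates kinds
        check_applicability("AI", kind)
        if noise is None:
            raise ParameterError("AI requires a noise model (sigma_bar^2)")
        ts = dx.sampling_interval
        ex = epochs(dx.values, ep, ts)
        ey = epochs(dy.values, ep, ts)
        ez = epochs(dz.values, ep, ts)
        vals = activity_index(ex, ey, ez, noise, variant=ai_variant)
        nv = noise.variance if isinstance(noise, NoiseModel) else float(noise)
        params["ai_variant"] = ai_variant
        params["noise_variance_g2"] = nv
        return ActivitySeries(values=vals, metric_id="AI", dataset_kind=kind,
                              epoch=ep, params=params, subject_id=subject_id)

    if not isinstance(data, DatasetSeries):
        raise ParameterError(
            f"{metric_id} operates on a single DatasetSeries")
    check_applicability(metric_id, data.kind)
    ts = data.sampling_interval
    win = epochs(data.values, ep, ts)

    thr_spec: Optional[ThresholdSpec] = None
    if metric_id in LEVEL_CROSSING_METRICS:
        if threshold is None:
            raise ParameterError(
                f"{metric_id} requires a threshold (fixed or SD-adaptive)")
        if isinstance(threshold, ThresholdSpec):
            thr_spec = threshold
        else:
            thr_spec = ThresholdSpec(
                value=float(threshold), mode="fixed",
                base_offset=1.0 if data.kind == "UFM" else 0.0,
                source_kind=data.kind)

    if metric_id in ("PIMr", "PIMs"):
        rule = "riemann" if metric_id == "PIMr" else "simpson38"
        if data.kind in PIM_RECTIFIED_KINDS:
            win = np.abs(win)
            params["rectified"] = True
        vals = pim(win, ts, rule=rule)
        if data.kind == "UFM" and baseline_subtract:
            vals = np.maximum(vals - win.shape[1] * ts, 0.0)
            params["baseline_subtract"] = True
        params["rule"] = rule
    elif metric_id == "ZCM":
        vals = zcm(win, thr_spec)
    elif metric_id == "TAT":
        vals = tat(win, thr_spec, ts)
    elif metric_id == "MAD":
        vals = mad(win)
    elif metric_id == "ENMO":
        vals = enmo(win)
    elif metric_id == "HFEN":
        vals = hfen(win)
    else:  # pragma: no cover - guarded by check_applicability
        raise ParameterError(f"unknown metric id {metric_id!r}")

    return ActivitySeries(values=np.atleast_1d(vals), metric_id=metric_id,
                          dataset_kind=data.kind, epoch=ep,
                          threshold=thr_spec, params=params,
                          subject_id=subject_id)


class ActivityTransformer(TransformerMixin, BaseEstimator):
    """One activity-signal definition as a scikit-learn transformer.

    X is raw triaxial acceleration in g, shape ``(n_samples, 3)`` (columns
    x, y, z).  ``fit`` derives the configured dataset and learns the
    data-dependent state: the SD-adaptive threshold for ZCM/TAT
    (``threshold_``) and the systematic noise variance for AI
    (``noise_variance_``).  ``transform`` re-derives the dataset and
    returns one activity value per epoch, shape ``(n_epochs, 1)``.

    Parameters
    ----------
    metric : str
        One of PIMr, PIMs, ZCM, TAT, MAD, ENMO, HFEN, AI.
    dataset : str
        Dataset kind the metric is applied to (UFM, UFNM, FMpre, FMpost,
        FX/FY/FZ, UFX/UFY/UFZ, HFEN_M; UFXYZ or FXYZ for AI).
    fs : float
        Sampling rate of X in Hz.
    epoch_length_s : float
        Epoch length T_e in seconds.
    threshold : "sd" or float or None
        Level for ZCM/TAT: ``"sd"`` learns the SD-adaptive level at fit
        time, a float fixes it (already including the 1 g base for UFM).
    """

    def __init__(self, metric: str = "ZCM", dataset: str = "UFNM",
                 fs: float = 10.0, epoch_length_s: float = 60.0,
                 threshold="sd", filter_order: int = 3,
                 filter_low_hz: float = 0.25, filter_high_hz: float = 2.5,
                 filter_mode: str = "causal", ai_variant: str = "linear",
                 noise_quantile: float = 0.01, range_g: float = 8.0):
        self.metric = metric
        self.dataset = dataset
        self.fs = fs
        self.epoch_length_s = epoch_length_s
        self.threshold = threshold
        self.filter_order = filter_order
        self.filter_low_hz = filter_low_hz
        self.filter_high_hz = filter_high_hz
        self.filter_mode = filter_mode
        self.ai_variant = ai_variant
        self.noise_quantile = noise_quantile
        self.range_g = range_g

    # -- helpers -----------------------------------------------------------

    def _recording(self, X) -> RawRecording:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ParameterError(
                f"X must have shape (n_samples, 3), got {X.shape}")
        return RawRecording(X[:, 0], X[:, 1], X[:, 2],
                            sampling_interval=1.0 / self.fs,
                            range_g=self.range_g)

    def _filter_spec(self) -> FilterSpec:
        return FilterSpec(kind="bandpass", low_cut_hz=self.filter_low_hz,
                          high_cut_hz=self.filter_high_hz,
                          order=self.filter_order, mode=self.filter_mode)

    def _dataset(self, rec: RawRecording):
        from .preprocess import build_datasets, hfen_magnitude
        if self.dataset == "HFEN_M":
            return hfen_magnitude(rec)
        sets = build_datasets(rec, self._filter_spec())
        if self.dataset in ("UFXYZ", "FXYZ"):
            names = (("UFX", "UFY", "UFZ") if self.dataset == "UFXYZ"
                     else ("FX", "FY", "FZ"))
            return [sets[n] for n in names]
        if self.dataset not in sets:
            raise ParameterError(f"unknown dataset {self.dataset!r}")
        return sets[self.dataset]

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None):
        from .thresholds import sd_threshold
        rec = self._recording(X)
        ep = EpochParams(self.epoch_length_s)
        check_applicability(self.metric, self.dataset)
        self.n_features_in_ = 3
        self.epoch_params_ = ep
        self.threshold_ = None
        self.noise_model_ = None
        if self.metric in LEVEL_CROSSING_METRICS:
            if self.threshold == "sd":
                self.threshold_ = sd_threshold(self._dataset(rec))
            elif self.threshold is None:
                raise ParameterError(
                    f"{self.metric} requires threshold='sd' or a number")
            else:
                base = 1.0 if self.dataset == "UFM" else 0.0
                self.threshold_ = ThresholdSpec(
                    value=float(self.threshold), mode="fixed",
                    base_offset=base, source_kind=self.dataset)
        if self.metric == "AI":
            self.noise_model_ = estimate_noise_variance(
                rec, ep, quantile=self.noise_quantile)
            self.noise_variance_ = self.noise_model_.variance
        return self

    def transform(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "epoch_params_")
        series = self.transform_series(X)
        return series.values[:, None]

    def transform_series(self, X, subject_id: Optional[str] = None
                         ) -> ActivitySeries:
        """Like :meth:`transform` but returns a full ActivitySeries."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "epoch_params_")
        rec = self._recording(X)
        data = self._dataset(rec)
        return compute_activity(
            data, self.metric, self.epoch_params_,
            threshold=self.threshold_, noise=self.noise_model_,
            ai_variant=self.ai_variant, subject_id=subject_id)

    def get_feature_names_out(self, input_features=None):
        return np.asarray([f"{self.metric}({self.dataset})"], dtype=object)
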