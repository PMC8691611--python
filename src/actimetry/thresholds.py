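"""Level-crossing threshold determination.

The recommended rule sets the ZCM/TAT threshold adaptively to the
population standard deviation of the *whole* dataset (not per epoch); for
the UFM dataset 1 g is added on top, because its values ride on the
constant gravity component.  The sweep machinery reproduces the analysis
that motivates the rule: activity signals are computed on a cumulative
threshold grid (default step 0.05 g, starting at the base offset) and
correlated with reference activity signals (typically ENMO and HFEN, which
admit only one computation each), tracing the rise-then-decay curves whose
maximum the SD rule approximates.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateThresholdWarning, ParameterError
from .metrics import LEVEL_CROSSING_METRICS, compute_activity
from .series import (ActivitySeries, DatasetSeries, EpochParams,
                     ThresholdSpec)


def sd_threshold(series: DatasetSeries) -> ThresholdSpec:
    """SD-adaptive threshold: population SD of the full series (+1 g for UFM).

    Emits :class:`DegenerateThresholdWarning` and returns the bare base
    offset when the series is constant.
    """
    if len(series) < 2:
        raise ParameterError("need at least 2 samples for an SD threshold")
    sd = float(np.std(series.values, ddof=0))
    base = 1.0 if series.kind == "UFM" else 0.0
    if np.all(series.values == series.values[0]):
        sd = 0.0
        warnings.warn(
            f"{series.kind} series is constant; SD-adaptive threshold "
            f"degenerates to its base offset {base:g} g",
            DegenerateThresholdWarning)
    return ThresholdSpec(value=base + sd, mode="sd_adaptive",
                         base_offset=base, source_kind=series.kind)


def threshold_sweep(series: DatasetSeries, metric_id: str,
                    ep: Optional[EpochParams] = None,
                    step_g: float = 0.05,
                    n_steps: int = 20) -> List[ActivitySeries]:
    """Activity series on the cumulative threshold grid.

    Thresholds are ``base_offset + k * step_g`` for k = 1..n_steps, where
    the base offset is 1 g for UFM and 0 g otherwise.
    """
    if metric_id not in LEVEL_CROSSING_METRICS:
        raise ParameterError(
            f"threshold sweep applies to ZCM/TAT, not {metric_id!r}")
    if not step_g > 0:
        raise ParameterError("step_g must be positive")
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    ep = ep if ep is not None else EpochParams()
    base = 1.0 if series.kind == "UFM" else 0.0
    out: List[ActivitySeries] = []
    for k in range(1, n_steps + 1):
        spec = ThresholdSpec(value=base + k * step_g, mode="sweep",
                             base_offset=base, source_kind=series.kind)
        out.append(compute_activity(series, metric_id, ep, threshold=spec))
    return out


def _corr_or_nan(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def sweep_correlation_curve(sweep: Sequence[ActivitySeries],
                            references: Sequence[ActivitySeries],
                            sd_signal: Optional[ActivitySeries] = None,
                            ) -> pd.DataFrame:
    """Pearson correlation of each sweep member against each reference.

    Returns a long-format table with columns ``threshold_g``,
    ``reference``, ``r`` and ``defined``.  ``sd_signal`` (the activity
    signal computed with the SD-adaptive threshold) adds a reference named
    ``"SD"`` — the red curve of the threshold-determination figures.
    Undefined correlations (a constant signal) are flagged with
    ``defined=False`` and ``r=NaN``, never silently dropped.
    """
    refs = [(ref.label, ref) for ref in references]
    if sd_signal is not None:
        refs.append(("SD", sd_signal))
    rows = []
    for member in sweep:
        if member.threshold is None:  # pragma: no cover - sweep always sets it
            raise ParameterError("sweep member lacks threshold provenance")
        for name, ref in refs:
            if len(ref) != len(member):
                raise ParameterError(
                    f"reference {name} has {len(ref)} epochs, sweep member "
                    f"has {len(member)}")
            r = _corr_or_nan(member.values, ref.values)
            rows.append({"threshold_g": member.threshold.value,
                         "reference": name, "r": r,
                         "defined": bool(np.isfinite(r))})
    return pd.DataFrame(rows)
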