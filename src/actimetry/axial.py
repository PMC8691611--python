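"""Merging per-axis activity signals into single indicators.

When a metric is applied to each axis separately, one indicator per epoch
can be formed from the three axial activity values: their sum, their sum of
squares, or the Euclidean combination VM3 = sqrt(a_x^2 + a_y^2 + a_z^2).
"""

from __future__ import annotations

import numpy as np

from .exceptions import AlignmentError, ParameterError
from .series import ActivitySeries

_AXIAL_SETS = ({"FX", "FY", "FZ"}, {"UFX", "UFY", "UFZ"})


def combine_axial(ax: ActivitySeries, ay: ActivitySeries,
                  az: ActivitySeries, method: str) -> ActivitySeries:
    """Combine three aligned axial activity series into one indicator.

    ``sum``: a_x + a_y + a_z; ``sum_sq``: a_x^2 + a_y^2 + a_z^2;
    ``vm3``: sqrt(a_x^2 + a_y^2 + a_z^2), per epoch.
    """
    if method not in ("sum", "sum_sq", "vm3"):
        raise ParameterError(f"unknown combination method {method!r}")
    triple = (ax, ay, az)
    kinds = {s.dataset_kind for s in triple}
    if kinds not in [set(s) for s in _AXIAL_SETS]:
        raise AlignmentError(
            f"inputs must be one series per axis of an axial triple, got "
            f"kinds {sorted(kinds)}")
    if len({s.metric_id for s in triple}) != 1:
        raise AlignmentError("axial series must share the metric")
    if len({s.epoch.epoch_length_s for s in triple}) != 1:
        raise AlignmentError("axial series must share the epoch length")
    if len({len(s) for s in triple}) != 1:
        raise AlignmentError("axial series must share the epoch grid")

    vx, vy, vz = (s.values for s in triple)
    if method == "sum":
        vals = vx + vy + vz
    elif method == "sum_sq":
        vals = vx ** 2 + vy ** 2 + vz ** 2
    else:
        vals = np.sqrt(vx ** 2 + vy ** 2 + vz ** 2)

    combined_kind = "FXYZ" if "FX" in kinds else "UFXYZ"
    params = {"axial_thresholds_g":
              [s.threshold.value for s in triple if s.threshold is not None]}
    return ActivitySeries(values=vals, metric_id=ax.metric_id,
                          dataset_kind=combined_kind, epoch=ax.epoch,
                          combination=method,
                          params=params if params["axial_thresholds_g"]
                          else {},
                          subject_id=ax.subject_id)
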