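"""Gait-derived behavioral metrics: left–right asymmetry and dual-task cost.

Both are percent quantities computed per gait parameter (arm-swing
amplitude, stride length, stride time, velocity, …); the functions are
parameter-agnostic and the table helpers operate on named columns following
the ``<measure>_right / _left / _st / _dt`` convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["asymmetry_percent", "dual_task_cost_percent",
           "add_gait_metrics"]


def asymmetry_percent(right, left):
    """(right − left) / max(right, left) × 100.

    Positive when the right side is larger; antisymmetric in its arguments;
    in [−100, 100] for non-negative inputs.  Undefined (NaN) when both
    sides are zero.
    """
    right = np.asarray(right, float)
    left = np.asarray(left, float)
    m = np.maximum(right, left)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(m > 0, (right - left) / m * 100.0, np.nan)
    return out if out.ndim else float(out)


def dual_task_cost_percent(dual_task, single_task):
    """(dual − single) / single × 100; negative means dual-task improvement."""
    dual = np.asarray(dual_task, float)
    single = np.asarray(single_task, float)
    if np.any(single <= 0):
        raise ValueError("single_task must be strictly positive")
    out = (dual - single) / single * 100.0
    return out if out.ndim else float(out)


def add_gait_metrics(table: pd.DataFrame, measures) -> pd.DataFrame:
    """Append ``<m>_asym`` and ``<m>_dtcost`` columns where the side / task
    columns exist for each named measure."""
    out = table.copy()
    for m in measures:
        if f"{m}_right" in out and f"{m}_left" in out:
            out[f"{m}_asym"] = asymmetry_percent(out[f"{m}_right"],
                                                 out[f"{m}_left"])
        if f"{m}_st" in out and f"{m}_dt" in out:
            out[f"{m}_dtcost"] = dual_task_cost_percent(out[f"{m}_dt"],
                                                        out[f"{m}_st"])
    return out
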