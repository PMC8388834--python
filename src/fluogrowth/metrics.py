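"""Scalar growth metrics per well/channel trace: AUC, maximum, final value.

The area under the curve (AUC) of a growth or fluorescence trace integrates
abundance over the observation window and is the workhorse summary here —
fitness is defined downstream as a ratio of AUCs.  Integration is the plain
trapezoid rule on the observed (blank-corrected) signal from the first to the
last finite timepoint, with no baseline anchoring: since fitness normalizes
by a monoculture AUC computed identically, any common baseline convention
cancels.  Missing readings are dropped pairwise with their timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .platedata import PlateLayout, PlateTimeSeries

__all__ = ["CurveMetrics", "curve_metrics", "metrics_table", "trapezoid_auc"]


@dataclass(frozen=True)
class CurveMetrics:
    auc: float          # signal * hours
    max_value: float
    final_value: float
    t_start: float      # hours, first finite point
    t_end: float        # hours, last finite point
    n_points: int


def _finite_pairs(times, values):
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise InsufficientDataError("times and values must be equal-length 1-D")
    keep = np.isfinite(v) & np.isfinite(t)
    t, v = t[keep], v[keep]
    if len(t) < 2:
        raise InsufficientDataError(
            f"need >=2 finite points, got {len(t)}"
        )
    if np.any(np.diff(t) <= 0):
        raise InsufficientDataError("times must be strictly increasing")
    return t, v


def trapezoid_auc(times, values) -> float:
    """Trapezoidal integral of ``values`` over ``times`` (hours).

    Exact for piecewise-linear traces.  Missing (NaN) values are dropped
    together with their timepoints before integration, i.e. the linear
    interpolant bridges the gap.
    """
    t, v = _finite_pairs(times, values)
    return float(np.trapezoid(v, t))


def curve_metrics(times, values) -> CurveMetrics:
    """AUC, maximum and final value of one trace (NaNs dropped)."""
    t, v = _finite_pairs(times, values)
    return CurveMetrics(
        auc=float(np.trapezoid(v, t)),
        max_value=float(np.max(v)),
        final_value=float(v[-1]),
        t_start=float(t[0]),
        t_end=float(t[-1]),
        n_points=int(len(t)),
    )


def metrics_table(
    ts: PlateTimeSeries,
    layout: PlateLayout,
    channels: list[str] | None = None,
) -> pd.DataFrame:
    """Per well x channel metrics for all sample wells.

    One row per (well, channel): plate, well, channel, strain, condition,
    replicate_group, auc, max, final, n_points.  For a fluorescence channel
    the strain is the one carrying that reporter in the well (the row is
    omitted if no strain in the well reports on the channel); for an
    absorbance channel all strains are joined with '+' since optical density
    cannot attribute growth to a strain.
    """
    channels = list(ts.channels) if channels is None else channels
    rows = []
    for well in ts.wells:
        spec = layout.wells.get(well)
        if spec is None or spec.role != "sample":
            continue
        for channel in channels:
            cdef = layout.channel(channel) if layout.channels else None
            if cdef is not None and cdef.kind == "fluorescence":
                strain = layout.strain_for_channel(well, channel)
                if strain is None:
                    continue
            else:
                strain = "+".join(n for n, _ in spec.strains)
            m = curve_metrics(ts.times_h, ts.trace(channel, well))
            rows.append(
                {
                    "plate": layout.plate_id,
                    "well": well,
                    "channel": channel,
                    "strain": strain,
                    "condition": spec.condition,
                    "replicate_group": spec.replicate_group,
                    "auc": m.auc,
                    "max": m.max_value,
                    "final": m.final_value,
                    "n_points": m.n_points,
                }
            )
    return pd.DataFrame(rows)
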