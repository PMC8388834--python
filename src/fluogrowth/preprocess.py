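"""Blank (background) correction of measurement channels.

Medium-only blank wells measure the baseline absorbance and autofluorescence
of the medium; subtracting them from sample wells isolates the biological
signal before any metric is computed.  Two modes are provided:

* ``per_timepoint`` (default) — subtract the mean of the blank wells at each
  timepoint, which tracks slow drift of the medium background.
* ``constant`` — subtract the grand mean of all blank readings.

Negative corrected values are retained, not clamped: clamping would bias the
area under the curve upward.  Blank wells themselves pass through unchanged.
Correction is deliberately not idempotent — a corrected channel is flagged
and re-correcting it raises, rather than silently shifting twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .platedata import PlateLayout, PlateTimeSeries

__all__ = ["CorrectionReport", "blank_correct"]

MODES = ("per_timepoint", "constant")


@dataclass
class CorrectionReport:
    """What was subtracted, from which blanks, and how it went.

    ``blank_mean`` has one entry per timepoint (in ``constant`` mode the
    grand mean is repeated).  ``negative_fraction`` is the fraction of
    corrected sample values that came out negative — a high value flags a
    blank brighter than the samples.
    """

    channel: str
    mode: str
    blank_wells_used: list[str]
    blank_mean: np.ndarray
    negative_fraction: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "channel": self.channel,
                "mode": self.mode,
                "blank_wells": ";".join(self.blank_wells_used),
                "blank_mean": self.blank_mean,
                "negative_fraction": self.negative_fraction,
            }
        )


def blank_correct(
    ts: PlateTimeSeries,
    layout: PlateLayout,
    channel: str,
    mode: str = "per_timepoint",
) -> tuple[PlateTimeSeries, CorrectionReport]:
    """Subtract the blank-well background from every sample well.

    Returns a new :class:`PlateTimeSeries` (input untouched) plus a
    :class:`CorrectionReport`.  Raises :class:`ConfigurationError` if the
    layout has no blank wells, the mode is unknown, or the channel was
    already corrected.
    """
    if mode not in MODES:
        raise ConfigurationError(f"unknown blank mode {mode!r}")
    if channel in ts.corrected:
        raise ConfigurationError(
            f"channel {channel!r} is already blank-corrected; "
            "re-correction would shift by the blank mean again"
        )
    blanks = [w for w in layout.blank_wells() if w in ts.wells]
    if not blanks:
        raise ConfigurationError(
            "blank correction requested but the layout has no blank wells "
            "present in the time series"
        )
    mat = ts.channel(channel)
    blank_rows = mat[[ts.well_index(w) for w in blanks], :]
    per_t = np.nanmean(blank_rows, axis=0)
    if mode == "constant":
        per_t = np.full_like(per_t, np.nanmean(blank_rows))

    corrected = mat.copy()
    sample_idx = [
        i for i, w in enumerate(ts.wells)
        if w in layout.wells and layout.wells[w].role == "sample"
    ]
    corrected[sample_idx, :] = mat[sample_idx, :] - per_t[np.newaxis, :]

    vals = corrected[sample_idx, :]
    finite = np.isfinite(vals)
    neg_frac = float(np.sum(vals[finite] < 0) / max(1, finite.sum()))

    data = dict(ts.data)
    data[channel] = corrected
    out = PlateTimeSeries(
        times_h=ts.times_h.copy(),
        wells=list(ts.wells),
        data=data,
        layout_ref=ts.layout_ref,
        corrected=ts.corrected | {channel},
    )
    report = CorrectionReport(
        channel=channel,
        mode=mode,
        blank_wells_used=list(blanks),
        blank_mean=per_t,
        negative_fraction=neg_frac,
    )
    return out, report
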