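"""Descriptive reduction of within-epoch information-processing curves.

Each epoch's curve (probe performance across time slices) is summarized by
four metrics plus one derived difference:

* ``start`` — performance at the first time slice: how much the very first
  segment of an item already reveals about its class.
* ``end`` — performance at the last time slice.
* ``max`` — the curve's maximum.
* ``t_max`` — fractional position of the (first) maximum, ``index / (T-1)``,
  so 0 means the peak sits at the first slice and 1 at the last.
* ``end_minus_start`` — the information gain across the item's presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .probe import LearningCurveSurface

__all__ = ["MetricRecord", "curve_metrics", "surface_metrics", "records_to_frame", "METRIC_NAMES"]

METRIC_NAMES = ("start", "end", "max", "t_max", "end_minus_start")


@dataclass
class MetricRecord:
    epoch: int
    start: float
    end: float
    max: float
    t_max: float
    end_minus_start: float
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "epoch": self.epoch, "start": self.start, "end": self.end,
            "max": self.max, "t_max": self.t_max,
            "end_minus_start": self.end_minus_start,
        }


def curve_metrics(curve, epoch: int, provenance: dict | None = None) -> MetricRecord:
    """Reduce one within-epoch performance curve to its descriptive metrics.

    Ties for the maximum resolve to the first (earliest) attaining slice.
    """
    c = np.asarray(curve, dtype=np.float64)
    if c.ndim != 1 or len(c) < 2:
        raise ValueError("curve must be 1-d with at least 2 time slices")
    if np.any(c < 0) or np.any(c > 1) or not np.all(np.isfinite(c)):
        raise ValueError("curve values must lie in [0, 1]")
    T = len(c)
    i_max = int(np.argmax(c))
    return MetricRecord(
        epoch=int(epoch),
        start=float(c[0]),
        end=float(c[-1]),
        max=float(c[i_max]),
        t_max=float(i_max / (T - 1)),
        end_minus_start=float(c[-1] - c[0]),
        provenance=dict(provenance or {}),
    )


def surface_metrics(surface: LearningCurveSurface) -> list[MetricRecord]:
    """One MetricRecord per epoch, in epoch order."""
    return [
        curve_metrics(surface.performance[e], int(surface.epochs[e]),
                      provenance=surface.provenance)
        for e in range(surface.n_epochs)
    ]


def records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    """Wide per-epoch frame with provenance columns prepended."""
    rows = []
    for r in records:
        row = {
            "dataset": r.provenance.get("dataset", "dataset"),
            "condition": r.provenance.get("condition", "ordered"),
            "label_pair": r.provenance.get("label_pair", "0/1"),
            "rep": r.provenance.get("rep", 0),
        }
        row.update(r.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
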