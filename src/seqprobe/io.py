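"""Long-format CSV interface for learning-curve surfaces and metric tables.

The curve schema has one row per (run, epoch, time slice):

``dataset,condition,label_pair,rep,epoch,time_slice,performance``

with ``time_slice`` 0-based, ``epoch`` 1-based, UTF-8, '.' decimal and full
float precision (round-trips bit-exactly).  Metric tables use the analysis
schema ``dataset,condition,label_pair,rep,epoch,metric,value``.  Unknown
extra columns are preserved on read.  A dialect flag on read accepts
1-based ``time_slice`` columns and rebases them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import MetricRecord
from .probe import LearningCurveSurface, ProbeConfig

__all__ = [
    "CURVE_COLUMNS",
    "METRIC_COLUMNS",
    "surface_to_long",
    "surfaces_to_long",
    "long_to_surfaces",
    "metric_records_to_long",
    "write_long_csv",
    "read_long_csv",
]

CURVE_COLUMNS = ("dataset", "condition", "label_pair", "rep", "epoch", "time_slice", "performance")
METRIC_COLUMNS = ("dataset", "condition", "label_pair", "rep", "epoch", "metric", "value")

_PROV_DEFAULTS = {"dataset": "dataset", "condition": "ordered", "label_pair": "0/1", "rep": 0}


def _provenance(prov: dict) -> dict:
    return {k: prov.get(k, v) for k, v in _PROV_DEFAULTS.items()}


def surface_to_long(surface: LearningCurveSurface) -> pd.DataFrame:
    """One row per (epoch, time slice) of a single run's surface."""
    prov = _provenance(surface.provenance)
    E, T = surface.performance.shape
    return pd.DataFrame({
        "dataset": prov["dataset"],
        "condition": prov["condition"],
        "label_pair": prov["label_pair"],
        "rep": prov["rep"],
        "epoch": np.repeat(surface.epochs, T),
        "time_slice": np.tile(surface.timesteps, E),
        "performance": surface.performance.ravel(),
    })


def surfaces_to_long(surfaces) -> pd.DataFrame:
    frames = [surface_to_long(s) for s in surfaces]
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(
        ["dataset", "label_pair", "rep", "epoch", "time_slice"]
    ).reset_index(drop=True)


def long_to_surfaces(df: pd.DataFrame) -> list[LearningCurveSurface]:
    """Reassemble surfaces, one per (dataset, condition, label_pair, rep)."""
    _check_curve_frame(df)
    out = []
    keys = ["dataset", "condition", "label_pair", "rep"]
    for key, grp in df.groupby(keys, sort=True):
        pivot = grp.pivot_table(
            index="epoch", columns="time_slice", values="performance", sort=True
        )
        out.append(LearningCurveSurface(
            performance=pivot.to_numpy(),
            epochs=pivot.index.to_numpy(),
            timesteps=pivot.columns.to_numpy(),
            probe=ProbeConfig(),
            provenance=dict(zip(keys, key)),
        ))
    return out


def metric_records_to_long(records: list[MetricRecord]) -> pd.DataFrame:
    """Tidy metric rows: one per (run, epoch, metric name)."""
    rows = []
    for r in records:
        prov = _provenance(r.provenance)
        for name, value in (
            ("start", r.start), ("end", r.end), ("max", r.max),
            ("t_max", r.t_max), ("end_minus_start", r.end_minus_start),
        ):
            rows.append({**prov, "epoch": r.epoch, "metric": name, "value": value})
    df = pd.DataFrame(rows, columns=list(METRIC_COLUMNS))
    return df.sort_values(
        ["dataset", "label_pair", "rep", "epoch", "metric"]
    ).reset_index(drop=True)


def write_long_csv(table, path: str | Path) -> Path:
    """Write a curve or metric long table (or a list of surfaces) to CSV."""
    if isinstance(table, LearningCurveSurface):
        table = surface_to_long(table)
    elif isinstance(table, (list, tuple)):
        if table and isinstance(table[0], LearningCurveSurface):
            table = surfaces_to_long(table)
        elif table and isinstance(table[0], MetricRecord):
            table = metric_records_to_long(table)
        else:
            raise TypeError("cannot serialize this list; expected surfaces or metric records")
    if not isinstance(table, pd.DataFrame):
        raise TypeError(f"cannot serialize {type(table).__name__}")
    if "performance" in table.columns:
        sort_cols = ["dataset", "label_pair", "rep", "epoch", "time_slice"]
    else:
        sort_cols = ["dataset", "label_pair", "rep", "epoch", "metric"]
    table = table.sort_values([c for c in sort_cols if c in table.columns])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # repr-precision floats so values round-trip bit-exactly
    table.to_csv(path, index=False, float_format=None)
    return path


def read_long_csv(path: str | Path, time_slice_base: int = 0) -> pd.DataFrame:
    """Read a long-format CSV, validating schema and value ranges.

    ``time_slice_base=1`` accepts files whose time slices are 1-based and
    rebases them to 0.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    is_curve = "performance" in df.columns
    required = CURVE_COLUMNS if is_curve else METRIC_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    value_col = "performance" if is_curve else "value"
    values = pd.to_numeric(df[value_col], errors="coerce")
    bad = np.flatnonzero(values.isna() & df[value_col].notna())
    if len(bad):
        raise ValueError(
            f"{path}: non-numeric {value_col} at data row {bad[0] + 1}"
        )
    if values.isna().any():
        raise ValueError(f"{path}: empty {value_col} values")
    df[value_col] = values
    lo = -1.0 if value_col == "value" else 0.0
    if (values < lo).any() or (values > 1.0).any():
        row = int(np.flatnonzero((values < lo) | (values > 1.0))[0]) + 1
        raise ValueError(
            f"{path}: {value_col} outside [{lo}, 1] at data row {row}"
        )
    if is_curve:
        df["time_slice"] = df["time_slice"].astype(int) - time_slice_base
        if (df["time_slice"] < 0).any():
            raise ValueError(f"{path}: negative time_slice after rebasing")
    df["epoch"] = df["epoch"].astype(int)
    return df


def _check_curve_frame(df: pd.DataFrame) -> None:
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"curve table missing column(s): {missing}")
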