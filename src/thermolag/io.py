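"""Readers and writers for the pipeline's plain-text table formats.

Formats (all comma-separated, header row, UTF-8):

* long-format OD table: ``well, time_h, od``
* plate map: ``well, strain, condition, replicate, carbon_source``
* kill-curve table: ``duration_min, colonies, dilution_factor,
  plated_volume_ul`` with an optional ``replicate`` column

Conditions are free-form strings; the canonical labels used by the pipeline
are ``ref30`` (30 degC reference growth), ``elevated35`` (continuous growth
at 35 degC) and ``heatshock30`` (recovery at 30 degC after heat shock).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .growth import CurveMeta, GrowthCurve
from .viability import KillCurvePoint

__all__ = [
    "COND_REFERENCE",
    "COND_ELEVATED",
    "COND_HEATSHOCK",
    "OD_COLUMNS",
    "MAP_COLUMNS",
    "KILL_COLUMNS",
    "curves_to_frames",
    "frames_to_curves",
    "write_curves",
    "read_curves",
    "read_kill_table",
    "write_kill_table",
]

COND_REFERENCE = "ref30"
COND_ELEVATED = "elevated35"
COND_HEATSHOCK = "heatshock30"

OD_COLUMNS = ["well", "time_h", "od"]
MAP_COLUMNS = ["well", "strain", "condition", "replicate", "carbon_source"]
KILL_COLUMNS = ["duration_min", "colonies", "dilution_factor", "plated_volume_ul"]


def _require_columns(frame: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns {missing}")


def curves_to_frames(
    curves: Iterable[GrowthCurve],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten curves into the long OD table and the plate map.

    Every curve must carry a unique well label; duplicate (well, time) rows
    are rejected because they make the long format ambiguous.
    """
    od_rows = []
    map_rows = []
    seen_wells: set[str] = set()
    for curve in curves:
        meta = curve.meta
        if not meta.well:
            raise ValueError("every curve needs a well label before writing")
        if meta.well in seen_wells:
            raise ValueError(f"duplicate well label {meta.well!r}")
        seen_wells.add(meta.well)
        map_rows.append(
            {
                "well": meta.well,
                "strain": meta.strain,
                "condition": meta.condition,
                "replicate": meta.replicate,
                "carbon_source": meta.carbon_source,
            }
        )
        for t, od in zip(curve.time_h, curve.od):
            od_rows.append({"well": meta.well, "time_h": t, "od": od})
    od_frame = pd.DataFrame(od_rows, columns=OD_COLUMNS)
    map_frame = pd.DataFrame(map_rows, columns=MAP_COLUMNS)
    if od_frame.duplicated(subset=["well", "time_h"]).any():
        raise ValueError("duplicate (well, time_h) rows in OD table")
    return od_frame, map_frame


def frames_to_curves(
    od_frame: pd.DataFrame, map_frame: pd.DataFrame
) -> list[GrowthCurve]:
    """Assemble curves from the long OD table and plate map.

    Raises if the OD table is empty, contains duplicate (well, time) rows,
    or references wells absent from the plate map (listing them).
    """
    _require_columns(od_frame, OD_COLUMNS, "OD table")
    _require_columns(map_frame, MAP_COLUMNS, "plate map")
    if od_frame.empty:
        raise ValueError("OD table contains no rows")
    if od_frame.duplicated(subset=["well", "time_h"]).any():
        raise ValueError("duplicate (well, time_h) rows in OD table")
    mapped = set(map_frame["well"].astype(str))
    present = set(od_frame["well"].astype(str))
    unmapped = sorted(present - mapped)
    if unmapped:
        raise ValueError(f"OD table contains unmapped wells: {unmapped}")

    meta_by_well = {
        str(row.well): CurveMeta(
            well=str(row.well),
            strain=str(row.strain),
            condition=str(row.condition),
            replicate=int(row.replicate),
            carbon_source=str(row.carbon_source),
        )
        for row in map_frame.itertuples()
    }
    curves = []
    for well, group in od_frame.groupby("well", sort=True):
        group = group.sort_values("time_h")
        curves.append(
            GrowthCurve(
                time_h=group["time_h"].to_numpy(dtype=float),
                od=group["od"].to_numpy(dtype=float),
                meta=meta_by_well[str(well)],
            )
        )
    return curves


def write_curves(
    curves: Iterable[GrowthCurve],
    od_path: str | os.PathLike,
    map_path: str | os.PathLike,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write the OD CSV and plate-map CSV; returns the frames written."""
    od_frame, map_frame = curves_to_frames(curves)
    od_frame.to_csv(od_path, index=False)
    map_frame.to_csv(map_path, index=False)
    return od_frame, map_frame


def read_curves(
    od_path: str | os.PathLike, map_path: str | os.PathLike
) -> list[GrowthCurve]:
    """Read curves from the OD CSV + plate-map CSV pair."""
    od_frame = pd.read_csv(od_path)
    map_frame = pd.read_csv(map_path)
    return frames_to_curves(od_frame, map_frame)


def read_kill_table(path: str | os.PathLike) -> list[KillCurvePoint]:
    """Read spot-plating observations from a kill-curve CSV."""
    frame = pd.read_csv(path)
    _require_columns(frame, KILL_COLUMNS, "kill-curve table")
    if frame.empty:
        raise ValueError("kill-curve table contains no rows")
    has_replicate = "replicate" in frame.columns
    points = []
    for row in frame.itertuples():
        points.append(
            KillCurvePoint(
                duration_min=float(row.duration_min),
                colonies=int(row.colonies),
                dilution_factor=float(row.dilution_factor),
                plated_volume_ul=float(row.plated_volume_ul),
                replicate=int(row.replicate) if has_replicate else 1,
            )
        )
    return points


def write_kill_table(
    points: Iterable[KillCurvePoint], path: str | os.PathLike
) -> pd.DataFrame:
    """Write spot-plating observations to a kill-curve CSV."""
    rows = [
        {
            "duration_min": p.duration_min,
            "colonies": p.colonies,
            "dilution_factor": p.dilution_factor,
            "plated_volume_ul": p.plated_volume_ul,
            "replicate": p.replicate,
        }
        for p in points
    ]
    frame = pd.DataFrame(rows, columns=KILL_COLUMNS + ["replicate"])
    if frame.empty:
        raise ValueError("no kill-curve points to write")
    frame.to_csv(path, index=False)
    return frame
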