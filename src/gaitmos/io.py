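"""CSV dialects for markers, IMU recordings, events, labels and results.

All files are plain CSV with SI units (metres, seconds, m/s^2, rad/s);
millimetres appear only in step-label and result files, matching how the
margins are reported.  Readers validate rather than coerce: missing
columns raise :class:`SchemaError` naming the column, malformed values
raise :class:`DataError` naming the row.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError
from .evaluate import CvResult, PlacementGrid
from .types import (
    IMU_CHANNELS,
    MARKER_NAMES,
    DesignMatrix,
    HeelContactSeries,
    ImuRecording,
    MarkerFrameSeries,
    StepLabel,
    step_labels_to_frame,
)

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


def _read_csv(path: Path | str, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _check_time_column(df: pd.DataFrame, path: Path | str) -> np.ndarray:
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError(f"{path}: need at least 2 rows")
    diffs = np.diff(t)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        raise DataError(
            f"{path}: time_s not strictly increasing at row {int(bad[0]) + 2}"
        )
    return t


# --- markers ---------------------------------------------------------------

def marker_columns() -> List[str]:
    return [f"{m}_{ax}" for m in MARKER_NAMES for ax in "xyz"]


def read_markers(path: Path | str) -> MarkerFrameSeries:
    """Read a marker CSV (time_s + 12 position columns, metres)."""
    df = _read_csv(path, ["time_s"] + marker_columns())
    t = _check_time_column(df, path)
    positions = {
        m: df[[f"{m}_x", f"{m}_y", f"{m}_z"]].to_numpy(dtype=float)
        for m in MARKER_NAMES
    }
    return MarkerFrameSeries(time=t, positions=positions)


def write_markers(markers: MarkerFrameSeries, path: Path | str) -> None:
    data = {"time_s": markers.time}
    for m in MARKER_NAMES:
        for i, ax in enumerate("xyz"):
            data[f"{m}_{ax}"] = markers.positions[m][:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


# --- IMU -------------------------------------------------------------------

def read_imu(path: Path | str, site: Optional[str] = None) -> ImuRecording:
    """Read a 6-axis IMU CSV; site from the ``site`` column or filename."""
    path = Path(path)
    df = _read_csv(path, ["time_s"] + list(IMU_CHANNELS))
    t = _check_time_column(df, path)
    if site is None:
        if "site" in df.columns:
            values = df["site"].unique()
            if len(values) != 1:
                raise DataError(f"{path}: multiple site labels {values}")
            site = str(values[0])
        else:
            site = path.stem
    return ImuRecording(
        site=site,
        time=t,
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
    )


def write_imu(rec: ImuRecording, path: Path | str) -> None:
    data = {"time_s": rec.time}
    for i, ch in enumerate(IMU_CHANNELS[:3]):
        data[ch] = rec.accel[:, i]
    for i, ch in enumerate(IMU_CHANNELS[3:]):
        data[ch] = rec.gyro[:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


# --- events ----------------------------------------------------------------

def read_events(path: Path | str) -> HeelContactSeries:
    df = _read_csv(path, ["time_s", "foot"])
    return HeelContactSeries(
        times=df["time_s"].to_numpy(dtype=float),
        feet=df["foot"].to_numpy(dtype=object),
    )


def write_events(events: HeelContactSeries, path: Path | str) -> None:
    events.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


# --- step labels -----------------------------------------------------------

LABEL_COLUMNS = [
    "participant",
    "speed_kmh",
    "support_foot",
    "step_index",
    "min_anterior_mm",
    "min_mediolateral_mm",
]


def read_step_labels(path: Path | str) -> pd.DataFrame:
    return _read_csv(path, LABEL_COLUMNS)


def write_step_labels(labels, path: Path | str) -> None:
    df = labels if isinstance(labels, pd.DataFrame) else step_labels_to_frame(labels)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# --- design matrices -------------------------------------------------------

def write_design_matrix(dm: DesignMatrix, path: Path | str) -> None:
    """Design-matrix CSV: metadata columns, y (mm), then x000..x{d-1}."""
    meta = dm.meta.reset_index(drop=True).copy()
    meta["y"] = dm.y
    width = max(3, len(str(dm.X.shape[1] - 1)))
    xcols = pd.DataFrame(
        dm.X, columns=[f"x{i:0{width}d}" for i in range(dm.X.shape[1])]
    )
    out = pd.concat([meta, xcols], axis=1)
    out.attrs["sites"] = dm.sites
    header = (
        f"# gaitmos design matrix: sites={','.join(dm.sites)} "
        f"direction={dm.direction} support={dm.support_foot}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        out.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_design_matrix(path: Path | str) -> DesignMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# gaitmos design matrix:"):
            raise SchemaError(f"{path}: missing design-matrix header line")
        fields = dict(
            part.split("=", 1) for part in first.split(":", 1)[1].split()
        )
        df = pd.read_csv(fh)
    for col in ("participant", "speed_kmh", "support_foot", "step_index", "y"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column(s) {col}")
    xcols = [c for c in df.columns if c.startswith("x") and c[1:].isdigit()]
    sites = tuple(s for s in fields.get("sites", "").split(",") if s)
    return DesignMatrix(
        X=df[xcols].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        meta=df[["participant", "speed_kmh", "support_foot", "step_index"]],
        sites=sites,
        direction=fields.get("direction", "anterior"),
        support_foot=fields.get("support", "left"),
    )


# --- results ---------------------------------------------------------------

def write_cv_result(res: CvResult, path: Path | str) -> None:
    pd.DataFrame(
        {
            "repetition": np.repeat(np.arange(res.repetitions), res.k),
            "fold": np.tile(np.arange(res.k), res.repetitions),
            "L": res.L,
            "rmse_mm": res.rmse_values,
            "corr": res.corr_values,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_placement_grid(grid: PlacementGrid, path: Path | str) -> None:
    """Tidy CSV, one row per cell; deterministic (sorted) row order."""
    grid.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def render_placement_matrix(grid: PlacementGrid) -> str:
    """Text rendering of the triangular grid (single sites on the diagonal)."""
    sites = list(grid.sites)
    colw = max(len(s) for s in sites) + 2
    lines = [
        f"{grid.direction} MoS, {grid.support_foot} support "
        "(RMSE mean+/-sd mm, correlation in parentheses)"
    ]
    header = " " * colw + "".join(f"{s:>{colw}}" for s in sites)
    lines.append(header)
    for i, a in enumerate(sites):
        cells = []
        for j, b in enumerate(sites):
            if j < i:
                cells.append(" " * colw)
            else:
                res = grid.cell(a, b)
                cells.append(
                    f"{res.rmse_mean:.0f}+/-{res.rmse_sd:.0f}"
                    f"({res.corr_mean:.2f})".rjust(colw)
                )
        lines.append(f"{a:<{colw}}" + "".join(cells))
    return "\n".join(lines)
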