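"""Shared in-memory containers for the gait-stability pipeline.

Coordinate convention (fixed throughout the package): lab frame with
``x`` mediolateral (+right), ``y`` anterior (walking direction), ``z``
vertical up with ``z = 0`` at the belt surface.  Internal units are SI
(metres, seconds); per-step minimum-MoS labels are reported in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

#: the four reference markers of the reduced marker set
MARKER_NAMES: Tuple[str, ...] = ("ASIS_L", "ASIS_R", "TOE_L", "TOE_R")

#: 6-axis IMU channel order used everywhere (accelerometer then gyroscope)
IMU_CHANNELS: Tuple[str, ...] = ("ax", "ay", "az", "gx", "gy", "gz")

#: number of normalized time points per step (0..50 % of the gait cycle)
N_GRID: int = 51

#: the ten candidate attachment sites, in canonical order
DEFAULT_SITES: Tuple[str, ...] = (
    "xiphisternum",
    "sacral_crest",
    "right_knee",
    "left_knee",
    "right_thigh",
    "left_thigh",
    "right_instep",
    "left_instep",
    "left_wrist",
    "skull_vertex",
)

_TIME_JITTER = 1e-6  # tolerated deviation (s) from a uniform grid


def _check_uniform_time(time: np.ndarray, what: str) -> None:
    if time.ndim != 1 or time.size < 2:
        raise DataError(f"{what}: need a 1-D time vector with >= 2 samples")
    dt = np.diff(time)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise DataError(
            f"{what}: time not strictly increasing at row {int(bad[0]) + 1}"
        )
    if np.max(np.abs(dt - dt[0])) > _TIME_JITTER:
        raise DataError(f"{what}: time grid not uniform within {_TIME_JITTER} s")


@dataclass
class MarkerFrameSeries:
    """Time-stamped lab-frame positions of the four reference markers.

    ``positions`` maps marker name -> (n, 3) array of [x, y, z] in metres.
    """

    time: np.ndarray
    positions: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        _check_uniform_time(self.time, "markers")
        missing = [m for m in MARKER_NAMES if m not in self.positions]
        if missing:
            raise SchemaError(f"missing markers: {', '.join(missing)}")
        for name in MARKER_NAMES:
            p = np.asarray(self.positions[name], dtype=float)
            if p.shape != (self.time.size, 3):
                raise DataError(
                    f"marker {name}: expected shape {(self.time.size, 3)}, "
                    f"got {p.shape}"
                )
            if np.any(p[:, 2] < -1e-9):
                raise DataError(f"marker {name}: z below belt surface")
            self.positions[name] = p

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def rate_hz(self) -> float:
        return 1.0 / self.dt

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass
class ImuRecording:
    """One body site's 6-axis recording: 3-axis accel (m/s^2) + gyro (rad/s)."""

    site: str
    time: np.ndarray
    accel: np.ndarray  # (n, 3)
    gyro: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        _check_uniform_time(self.time, f"imu[{self.site}]")
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.time.size
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise DataError(
                f"imu[{self.site}]: accel/gyro must be (n, 3) with n={n}"
            )

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def channels(self) -> np.ndarray:
        """Return the (n, 6) channel matrix in canonical ax..gz order."""
        return np.hstack([self.accel, self.gyro])

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass
class HeelContactSeries:
    """Sorted heel-contact events; feet must alternate strictly."""

    times: np.ndarray
    feet: np.ndarray  # array of "left"/"right"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.feet = np.asarray(self.feet, dtype=object)
        if self.times.ndim != 1 or self.times.shape != self.feet.shape:
            raise DataError("events: times and feet must be equal-length 1-D")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise DataError("events: times must be strictly increasing")
        for f in self.feet:
            if f not in ("left", "right"):
                raise DataError(f"events: unknown foot label {f!r}")
        same = [
            i
            for i in range(1, self.feet.size)
            if self.feet[i] == self.feet[i - 1]
        ]
        if same:
            raise DataError(
                f"events: feet do not alternate at event {same[0]} "
                f"(t={self.times[same[0]]:.3f} s)"
            )

    def __len__(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "foot": self.feet})


@dataclass
class MosSeries:
    """Frame-wise margin of stability; anterior signed, mediolateral >= 0."""

    time: np.ndarray
    anterior: np.ndarray  # signed margin, m
    mediolateral: np.ndarray  # absolute margin, m

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.anterior = np.asarray(self.anterior, dtype=float)
        self.mediolateral = np.asarray(self.mediolateral, dtype=float)
        n = self.time.size
        if self.anterior.shape != (n,) or self.mediolateral.shape != (n,):
            raise DataError("MosSeries: component length mismatch")
        if np.any(self.mediolateral < 0):
            raise DataError("MosSeries: mediolateral margin must be >= 0")


@dataclass(frozen=True)
class StepLabel:
    """Per-step minimum MoS in both directions (reported in millimetres)."""

    participant: int
    speed_kmh: float
    support_foot: str
    step_index: int
    min_anterior_mm: float
    min_mediolateral_mm: float


def step_labels_to_frame(labels: List[StepLabel]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in labels])


@dataclass
class StepSample:
    """One support-foot step: per-site 51 x 6 arrays plus the MoS labels."""

    participant: int
    speed_kmh: float
    support_foot: str
    step_index: int
    arrays: Dict[str, np.ndarray]  # site -> (N_GRID, 6)
    min_anterior_mm: float
    min_mediolateral_mm: float

    def __post_init__(self) -> None:
        for site, arr in self.arrays.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (N_GRID, len(IMU_CHANNELS)):
                raise DataError(
                    f"step sample site {site}: expected "
                    f"{(N_GRID, len(IMU_CHANNELS))}, got {arr.shape}"
                )
            self.arrays[site] = arr

    def label(self, direction: str) -> float:
        if direction == "anterior":
            return self.min_anterior_mm
        if direction == "mediolateral":
            return self.min_mediolateral_mm
        raise ValueError(f"unknown direction {direction!r}")


@dataclass
class DesignMatrix:
    """Predictor matrix X (n x 306*S) with aligned labels y (mm) and metadata."""

    X: np.ndarray
    y: np.ndarray
    meta: pd.DataFrame = field(repr=False)
    sites: Tuple[str, ...] = ()
    direction: str = "anterior"
    support_foot: str = "left"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.X.shape[0]
        if self.y.shape != (n,) or len(self.meta) != n:
            raise DataError("DesignMatrix: X, y and meta lengths differ")
        expected = N_GRID * len(IMU_CHANNELS) * len(self.sites)
        if self.sites and self.X.shape[1] != expected:
            raise DataError(
                f"DesignMatrix: expected {expected} columns for sites "
                f"{self.sites}, got {self.X.shape[1]}"
            )

    def __len__(self) -> int:
        return int(self.X.shape[0])
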