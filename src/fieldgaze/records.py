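"""Typed in-memory records for every stream the pipeline touches.

Timestamps are decimal seconds on each *device's own clock*; cross-device
alignment is an explicit, separate stage (`stream_alignment`), never an I/O
side effect — the clock offset between the GPS logger and the eye tracker is
a first-class quantity in this pipeline, not something to hide in a reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import EmptyInputError, OrderingError, RangeError

GPS_COLUMNS = ["t", "lat", "lon", "quality", "n_satellites", "precision"]

#: RTK fix-quality code for an uncorrected single (autonomous) solution.
SINGLE_SOLUTION_QUALITY = 5


def _check_monotonic(t: np.ndarray, what: str) -> None:
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        i = int(bad[0]) + 1
        raise OrderingError(
            f"{what}: timestamps not strictly increasing at row {i} "
            f"(t[{i - 1}]={t[i - 1]!r}, t[{i}]={t[i]!r})"
        )


@dataclass
class GeoTrack:
    """Time-ordered positional fixes with per-fix quality metadata.

    ``data`` columns: t (s, device clock), lat, lon (degrees WGS84),
    quality (int code, NaN if unknown), n_satellites (count, NaN if unknown),
    precision (m, camera source only, NaN otherwise). An optional boolean
    ``interpolated`` column marks fixes reconstructed during cleaning.
    """

    data: pd.DataFrame
    source: str = "rtk"
    n_rejected: int = 0

    def __post_init__(self) -> None:
        for col in GPS_COLUMNS:
            if col not in self.data.columns:
                self.data[col] = np.nan
        self.data = self.data.reset_index(drop=True)
        t = self.data["t"].to_numpy(dtype=float)
        _check_monotonic(t, "GeoTrack")
        lat = self.data["lat"].to_numpy(dtype=float)
        lon = self.data["lon"].to_numpy(dtype=float)
        if np.any((lat < -90) | (lat > 90)):
            raise RangeError("latitude outside [-90, 90]")
        if np.any((lon < -180) | (lon > 180)):
            raise RangeError("longitude outside [-180, 180]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.data["lat"].to_numpy(dtype=float)

    @property
    def lon(self) -> np.ndarray:
        return self.data["lon"].to_numpy(dtype=float)

    def crop(self, t_start: float, t_end: float) -> "GeoTrack":
        """Fixes with t_start <= t < t_end, preserving metadata."""
        mask = (self.data["t"] >= t_start) & (self.data["t"] < t_end)
        return GeoTrack(self.data.loc[mask].copy(), source=self.source)


@dataclass
class ImuTrace:
    """Time-ordered head-tracker samples at a nominal 110 Hz.

    ``data`` columns: t (s, device clock), yaw (signed degrees in
    (−180, 180], the magnetometer-referenced directional output).
    """

    data: pd.DataFrame
    nominal_rate_hz: float = 110.0

    def __post_init__(self) -> None:
        if len(self.data) == 0:
            raise EmptyInputError("ImuTrace requires at least one sample")
        self.data = self.data.reset_index(drop=True)
        _check_monotonic(self.data["t"].to_numpy(dtype=float), "ImuTrace")
        yaw = self.data["yaw"].to_numpy(dtype=float)
        if np.any((yaw <= -180.0) | (yaw > 180.0)):
            raise RangeError("yaw outside (-180, 180]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy(dtype=float)

    @property
    def yaw(self) -> np.ndarray:
        return self.data["yaw"].to_numpy(dtype=float)

    @property
    def estimated_rate_hz(self) -> float:
        if len(self.data) < 2:
            return float("nan")
        t = self.t
        return (len(t) - 1) / (t[-1] - t[0])


@dataclass(frozen=True)
class TargetAnnotation:
    """One manually annotated validation-target bounding box in one frame."""

    recording_id: str
    target: int
    frame: int
    x: float
    y: float
    w: float
    h: float
    target_size_cm: float = 12.0
    viewing_distance_cm: float = 300.0

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def target_size_px(self) -> float:
        """Pixel diameter of the (circular) physical target: the larger box
        side, robust to partial occlusion of the handheld target."""
        return float(max(self.w, self.h))


@dataclass
class ValidationScene:
    """Gaze samples plus annotated target boxes for one 10-target validation.

    ``gaze``: columns t (s), x, y (px, 1600 × 1200 scene frame, origin
    top-left). ``annotations``: one row per (target, frame) with columns
    recording_id, target, frame, x, y, w, h. Frame f of the scene video
    exposes the half-open interval [f/fps, (f+1)/fps).
    """

    gaze: pd.DataFrame
    annotations: pd.DataFrame
    recording_id: str = ""
    frame_rate_hz: float = 30.0
    frame_size: tuple[int, int] = (1600, 1200)
    target_size_cm: float = 12.0
    viewing_distance_cm: float = 300.0


@dataclass(frozen=True)
class CompassReading:
    """One compass photo read-out at a segment boundary."""

    session_id: str
    phase: str  # "start" | "end"
    heading_deg: float  # cardinal [0, 360)

    def __post_init__(self) -> None:
        if not (0.0 <= self.heading_deg < 360.0):
            raise RangeError(f"compass heading {self.heading_deg} outside [0, 360)")
        if self.phase not in ("start", "end"):
            raise RangeError(f"phase must be 'start' or 'end', got {self.phase!r}")


@dataclass(frozen=True)
class PointingTrial:
    """One compass read-out toward a known (or cardinal-north) target."""

    trial_id: str
    task: str  # "north" | "building"
    lat1: float
    lon1: float
    compass_reading_deg: float  # magnetic cardinal [0, 360)
    declination_deg: float = 0.0  # east-positive
    lat2: Optional[float] = None
    lon2: Optional[float] = None
    target_id: Optional[str] = None
    confidence: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.compass_reading_deg < 360.0):
            raise RangeError("compass reading outside [0, 360)")
        if self.task not in ("north", "building"):
            raise RangeError(f"task must be 'north' or 'building', got {self.task!r}")
        if self.task == "building" and (self.lat2 is None or self.lon2 is None):
            raise RangeError("building trials require a target location")
        if self.confidence is not None and not (0 <= self.confidence <= 10):
            raise RangeError("confidence outside 0-10")


@dataclass
class SessionManifest:
    """Per-session constants and stream file paths.

    ``session_id`` follows the study dialect "X_Y" (exploration 1–5,
    10-minute segment 1–3). ``declination_deg`` is east-positive and is
    *added* to a magnetic reading to obtain a true-north heading.
    """

    session_id: str
    planned_duration_min: float
    declination_deg: float = 0.0
    viewing_distance_cm: float = 300.0
    target_diameter_cm: float = 12.0
    streams: dict = field(default_factory=dict)  # name -> resolved Path
    gps_source: str = "rtk"
    anchors: dict = field(default_factory=dict)  # gps_anchor_s / imu_anchor_s
    exploration_window_s: Optional[tuple[float, float]] = None  # IMU clock
    end_validation_anchor_s: Optional[float] = None  # IMU clock
    pointing_location: Optional[tuple[float, float]] = None
    pointing_targets: dict = field(default_factory=dict)  # id -> (lat, lon)

    def __post_init__(self) -> None:
        if self.planned_duration_min <= 0:
            raise RangeError("planned_duration_min must be > 0")
        if not (-30.0 <= self.declination_deg <= 30.0):
            raise RangeError("declination outside [-30, 30] degrees")
        for name, p in self.streams.items():
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"manifest stream {name!r}: {p} not found")
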