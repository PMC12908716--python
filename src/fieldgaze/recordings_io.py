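"""Readers and writers for every on-disk artifact the pipeline touches.

One delimited-text dialect throughout: comma-separated, UTF-8, mandatory
header row, "." decimal mark. GPX 1.1 is accepted as an alternative source
of positional tracks (action-camera exports); quality and satellite fields
absent from GPX are filled as unknown (NaN). Structured outputs (QC report,
alignment results, ground truth) are JSON.

Readers never silently drop rows: rows rejected for unparseable coordinates
are counted on the returned object and logged, and structural problems
(missing columns, non-monotonic timestamps, out-of-range values) raise.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import asdict
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyInputError, FormatError, RangeError
from .records import (
    GPS_COLUMNS,
    CompassReading,
    GeoTrack,
    ImuTrace,
    PointingTrial,
    SessionManifest,
)

log = logging.getLogger("fieldgaze.io")

PathLike = Union[str, Path]

_GPS_REQUIRED = {
    "rtk": ["timestamp", "lat", "lon", "quality", "n_satellites"],
    "camera": ["timestamp", "lat", "lon", "precision"],
}


def _read_csv(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return df


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_gps_table(path: PathLike, source: str = "rtk") -> GeoTrack:
    """Read a GPS fix table (CSV) into a GeoTrack.

    ``source='rtk'`` requires quality + n_satellites columns; ``'camera'``
    requires a precision column. Rows whose coordinates fail to parse are
    rejected (counted in ``GeoTrack.n_rejected`` and logged); timestamps must
    be strictly increasing after rejection.
    """
    if source not in _GPS_REQUIRED:
        raise FormatError(f"unknown GPS source {source!r}")
    df = _read_csv(path)
    _require_columns(df, _GPS_REQUIRED[source], path)
    n_rows = len(df)
    out = pd.DataFrame(
        {
            "t": pd.to_numeric(df["timestamp"], errors="coerce"),
            "lat": pd.to_numeric(df["lat"], errors="coerce"),
            "lon": pd.to_numeric(df["lon"], errors="coerce"),
        }
    )
    for col in ("quality", "n_satellites", "precision"):
        out[col] = (
            pd.to_numeric(df[col], errors="coerce") if col in df.columns else np.nan
        )
    ok = out[["t", "lat", "lon"]].notna().all(axis=1)
    n_rejected = int((~ok).sum())
    if n_rejected:
        log.warning("%s: rejected %d/%d rows with unparseable fields", path, n_rejected, n_rows)
    return GeoTrack(out.loc[ok], source=source, n_rejected=n_rejected)


def write_gps_table(track: GeoTrack, path: PathLike) -> None:
    df = track.data[GPS_COLUMNS].rename(columns={"t": "timestamp"})
    df.to_csv(path, index=False)


def read_gpx_track(path: PathLike) -> GeoTrack:
    """Read trackpoints from a GPX 1.1 file into a GeoTrack.

    Timestamps become POSIX seconds; fix quality and satellite counts are
    filled as unknown unless <sat> elements are present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"{path}: not well-formed XML: {exc}") from exc
    ns = {"gpx": "http://www.topografix.com/GPX/1/1"}
    rows = []
    for pt in root.iterfind(".//gpx:trkpt", ns):
        time_el = pt.find("gpx:time", ns)
        if time_el is None or time_el.text is None:
            continue
        ts = _dt.datetime.fromisoformat(time_el.text.replace("Z", "+00:00"))
        sat = pt.find("gpx:sat", ns)
        rows.append(
            {
                "t": ts.timestamp(),
                "lat": float(pt.attrib["lat"]),
                "lon": float(pt.attrib["lon"]),
                "quality": np.nan,
                "n_satellites": float(sat.text) if sat is not None else np.nan,
                "precision": np.nan,
            }
        )
    if not rows:
        raise EmptyInputError(f"{path}: no timestamped trackpoints")
    return GeoTrack(pd.DataFrame(rows), source="camera")


def write_gpx_track(track: GeoTrack, path: PathLike, name: str = "fieldgaze") -> None:
    """Write a GeoTrack as a minimal GPX 1.1 track (timestamps = POSIX s)."""
    gpx = ET.Element("gpx", version="1.1", creator="fieldgaze",
                     xmlns="http://www.topografix.com/GPX/1/1")
    trk = ET.SubElement(gpx, "trk")
    ET.SubElement(trk, "name").text = name
    seg = ET.SubElement(trk, "trkseg")
    for row in track.data.itertuples():
        pt = ET.SubElement(seg, "trkpt", lat=f"{row.lat:.8f}", lon=f"{row.lon:.8f}")
        ts = _dt.datetime.fromtimestamp(row.t, tz=_dt.timezone.utc)
        ET.SubElement(pt, "time").text = ts.isoformat().replace("+00:00", "Z")
        if np.isfinite(row.n_satellites):
            ET.SubElement(pt, "sat").text = str(int(row.n_satellites))
    ET.ElementTree(gpx).write(path, xml_declaration=True, encoding="unicode")


def read_imu_table(path: PathLike) -> ImuTrace:
    """Read an IMU yaw table (CSV: timestamp, yaw) into an ImuTrace."""
    df = _read_csv(path)
    if len(df) == 0:
        raise EmptyInputError(f"{path}: empty IMU table")
    _require_columns(df, ["timestamp", "yaw"], path)
    out = pd.DataFrame(
        {
            "t": pd.to_numeric(df["timestamp"], errors="raise"),
            "yaw": pd.to_numeric(df["yaw"], errors="raise"),
        }
    )
    return ImuTrace(out)


def write_imu_table(trace: ImuTrace, path: PathLike) -> None:
    trace.data.rename(columns={"t": "timestamp"}).to_csv(path, index=False)


def read_gaze_table(path: PathLike) -> pd.DataFrame:
    """Read gaze samples (CSV: timestamp, x, y) as a DataFrame (t, x, y)."""
    df = _read_csv(path)
    _require_columns(df, ["timestamp", "x", "y"], path)
    out = pd.DataFrame(
        {
            "t": pd.to_numeric(df["timestamp"], errors="raise"),
            "x": pd.to_numeric(df["x"], errors="raise"),
            "y": pd.to_numeric(df["y"], errors="raise"),
        }
    )
    if not np.isfinite(out.to_numpy()).all():
        raise FormatError(f"{path}: non-finite gaze sample")
    return out


def write_gaze_table(gaze: pd.DataFrame, path: PathLike) -> None:
    gaze.rename(columns={"t": "timestamp"}).to_csv(path, index=False)


def read_validation_annotations(path: PathLike, max_target: int = 10) -> pd.DataFrame:
    """Read target-box annotations into a DataFrame with box centers.

    Columns required: recording_id, target (1..max_target), frame, x, y, w, h
    (pixels). Adds cx, cy (box center) and size_px (larger box side).
    """
    df = _read_csv(path)
    _require_columns(df, ["recording_id", "target", "frame", "x", "y", "w", "h"], path)
    for col in ("target", "frame", "x", "y", "w", "h"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    tgt = df["target"].to_numpy()
    if np.any((tgt < 1) | (tgt > max_target)):
        bad = df.loc[(df["target"] < 1) | (df["target"] > max_target)].index[0]
        raise RangeError(
            f"{path}: target index outside 1-{max_target} at row {bad}"
        )
    if np.any(df["w"].to_numpy() <= 0) or np.any(df["h"].to_numpy() <= 0):
        raise FormatError(f"{path}: non-positive bounding-box extent")
    df = df.copy()
    df["cx"] = df["x"] + df["w"] / 2.0
    df["cy"] = df["y"] + df["h"] / 2.0
    df["size_px"] = df[["w", "h"]].max(axis=1)
    return df.sort_values(["recording_id", "target", "frame"]).reset_index(drop=True)


def write_validation_annotations(annotations: pd.DataFrame, path: PathLike) -> None:
    cols = ["recording_id", "target", "frame", "x", "y", "w", "h"]
    annotations[cols].to_csv(path, index=False)


def read_compass_readings(path: PathLike) -> list[CompassReading]:
    """Read compass read-outs (CSV: session_id, phase, heading)."""
    df = _read_csv(path)
    _require_columns(df, ["session_id", "phase", "heading"], path)
    return [
        CompassReading(str(r.session_id), str(r.phase), float(r.heading))
        for r in df.itertuples()
    ]


def write_compass_readings(readings, path: PathLike) -> None:
    pd.DataFrame(
        [
            {"session_id": r.session_id, "phase": r.phase, "heading": r.heading_deg}
            for r in readings
        ]
    ).to_csv(path, index=False)


def read_pointing_table(
    path: PathLike,
    location: tuple[float, float],
    targets: dict,
    declination_deg: float = 0.0,
) -> list[PointingTrial]:
    """Read a pointing-task survey export into PointingTrials.

    CSV columns: trial, task (north|building), target_id, compass_reading,
    confidence (may be blank). Participant and target coordinates come from
    the session manifest (stationary-task procedure), not from the GPS
    stream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"trial": str, "task": str, "target_id": str})
    _require_columns(df, ["trial", "task", "target_id", "compass_reading"], path)
    trials = []
    for r in df.itertuples():
        task = str(r.task)
        target_id = None if pd.isna(r.target_id) else str(r.target_id)
        if task == "building":
            if target_id not in targets:
                raise FormatError(f"{path}: unknown target_id {target_id!r}")
            lat2, lon2 = targets[target_id]
        else:
            lat2 = lon2 = None
        conf = getattr(r, "confidence", None)
        conf = None if conf is None or pd.isna(conf) else int(conf)
        trials.append(
            PointingTrial(
                trial_id=str(r.trial),
                task=task,
                lat1=location[0],
                lon1=location[1],
                lat2=lat2,
                lon2=lon2,
                target_id=target_id,
                compass_reading_deg=float(r.compass_reading),
                declination_deg=declination_deg,
                confidence=conf,
            )
        )
    return trials


def write_pointing_table(trials, path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "trial": tr.trial_id,
                "task": tr.task,
                "target_id": tr.target_id if tr.target_id is not None else "",
                "compass_reading": tr.compass_reading_deg,
                "confidence": "" if tr.confidence is None else tr.confidence,
            }
            for tr in trials
        ]
    ).to_csv(path, index=False)


# --- manifest ---------------------------------------------------------------

def load_manifest(path: PathLike) -> SessionManifest:
    """Load a session manifest from YAML or JSON.

    Stream paths are resolved relative to the manifest's directory and must
    exist at load time.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: manifest must be a mapping")
    base = path.parent
    streams = {
        name: (base / p) if p is not None else None
        for name, p in (raw.get("streams") or {}).items()
    }
    window = raw.get("exploration_window_s")
    return SessionManifest(
        session_id=str(raw["session_id"]),
        planned_duration_min=float(raw["planned_duration_min"]),
        declination_deg=float(raw.get("declination_deg", 0.0)),
        viewing_distance_cm=float(raw.get("viewing_distance_cm", 300.0)),
        target_diameter_cm=float(raw.get("target_diameter_cm", 12.0)),
        streams=streams,
        gps_source=str(raw.get("gps_source", "rtk")),
        anchors=dict(raw.get("anchors") or {}),
        exploration_window_s=tuple(window) if window else None,
        end_validation_anchor_s=raw.get("end_validation_anchor_s"),
        pointing_location=(
            tuple(raw["pointing_location"]) if raw.get("pointing_location") else None
        ),
        pointing_targets={
            str(k): tuple(v) for k, v in (raw.get("pointing_targets") or {}).items()
        },
    )


def _to_builtin(obj):
    """Recursively coerce numpy scalars/paths so YAML/JSON can emit them."""
    if isinstance(obj, dict):
        return {str(k): _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def save_manifest(manifest: SessionManifest, path: PathLike) -> None:
    d = asdict(manifest)
    d["streams"] = {
        k: (str(Path(v).name) if v is not None else None)
        for k, v in manifest.streams.items()
    }
    d["exploration_window_s"] = (
        list(manifest.exploration_window_s) if manifest.exploration_window_s else None
    )
    d["pointing_location"] = (
        list(manifest.pointing_location) if manifest.pointing_location else None
    )
    d["pointing_targets"] = {k: list(v) for k, v in manifest.pointing_targets.items()}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_to_builtin(d), fh, sort_keys=False)


# --- structured JSON artifacts ----------------------------------------------

def write_json(obj: dict, path: PathLike) -> None:
    """Write a JSON artifact atomically (write-then-rename)."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(_to_builtin(obj), fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    tmp.replace(path)


def read_json(path: PathLike) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
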