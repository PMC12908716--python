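"""Synthetic co-registered GPS / IMU / gaze / pointing sessions.

The field study's raw recordings were never deposited, so every pipeline
stage is exercised against simulated sessions with exhaustive ground truth.
The generators emulate the study conditions:

* a pedestrian walk at 3.35 ± 1.15 km/h (AR(1) speed, correlated random-walk
  heading on a local planar approximation re-projected to WGS84), with
  injectable multi-meter position jumps and quality/satellite degradations;
* a head-tracker yaw trace at 110 Hz containing a stationary lead-in, three
  360° calibration rotations, a high-amplitude serpentine oscillation, and a
  device clock offset of seconds relative to the GPS stream;
* 10-target gaze validations in a 1600 × 1200 scene frame with isotropic
  Gaussian gaze noise;
* pointing trials with known true bearings, wrapped-Gaussian angular noise
  and an optional monotone error→confidence link.

All generators are pure functions of (parameters, seed); sub-streams are
derived deterministically from the scenario seed. Timestamp convention:
the IMU clock is "true" time; the GPS stream's timestamps are true time
minus ``clock_offset_s``, so adding the offset back aligns GPS to IMU —
exactly what the alignment stage must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import recordings_io
from .circular import wrap_cardinal, wrap_signed
from .errors import ParameterError
from .records import (
    SINGLE_SOLUTION_QUALITY,
    CompassReading,
    GeoTrack,
    ImuTrace,
    PointingTrial,
    SessionManifest,
    ValidationScene,
)

EARTH_RADIUS_M = 6_371_000.0

#: Default simulation origin (Mediterranean coastal city, WGS84).
DEFAULT_ORIGIN = (34.675, 33.040)


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic independent substream of a scenario seed."""
    return np.random.default_rng([int(seed), int(stream)])


@dataclass(frozen=True)
class FaultSpec:
    """One injected GPS fault: a teleport and/or degraded fix metadata."""

    time_s: float  # true-clock time of the faulted fix
    displacement_m: float = 0.0
    quality: Optional[int] = None
    n_satellites: Optional[int] = None


@dataclass
class WalkScenario:
    """Parameters of one simulated session (seed + study conditions).

    Speeds are km/h; the walk phase uses an AR(1) speed process around
    ``mean_speed_kmh`` clipped symmetrically at ±2 sd (mean-preserving), and
    a correlated random-walk heading with per-second step sd
    ``heading_step_sd_deg``. The protocol phases before the walk — a short
    stationary hold, the 360° calibration rotations, and the serpentine
    synchronization bout — are part of every session, as in the field
    protocol.
    """

    seed: int = 0
    duration_s: float = 300.0  # exploration (walk) phase
    mean_speed_kmh: float = 3.35
    speed_sd_kmh: float = 1.15
    gps_rate_hz: float = 1.0
    faults: Sequence[FaultSpec] = ()
    clock_offset_s: float = 0.0
    origin: tuple[float, float] = DEFAULT_ORIGIN
    initial_heading_deg: float = 40.0
    heading_step_sd_deg: float = 18.0
    speed_ar1: float = 0.8
    position_jitter_m: float = 0.02
    hold_s: float = 2.0
    calibration_s: float = 12.0
    serpentine_s: float = 20.0
    tail_s: float = 2.0
    clean_quality: int = 1
    clean_satellites: int = 10

    def __post_init__(self) -> None:
        if self.mean_speed_kmh <= 0:
            raise ParameterError("mean_speed_kmh must be > 0")
        if self.gps_rate_hz <= 0:
            raise ParameterError("gps_rate_hz must be > 0")
        total = self.total_duration_s
        for f in self.faults:
            if not (0.0 <= f.time_s <= total):
                raise ParameterError(f"fault at {f.time_s}s outside [0, {total}]s")

    @property
    def total_duration_s(self) -> float:
        return self.hold_s + self.calibration_s + self.serpentine_s + self.duration_s + self.tail_s

    @property
    def phases(self) -> dict:
        """Phase boundaries on the true (IMU) clock."""
        t0 = 0.0
        t1 = t0 + self.hold_s
        t2 = t1 + self.calibration_s
        t3 = t2 + self.serpentine_s
        t4 = t3 + self.duration_s
        t5 = t4 + self.tail_s
        return {
            "hold": (t0, t1),
            "calibration": (t1, t2),
            "serpentine": (t2, t3),
            "walk": (t3, t4),
            "tail": (t4, t5),
        }


@dataclass(frozen=True)
class SerpentineSpec:
    """Yaw oscillation of the synchronization bout."""

    amplitude_deg: float = 75.0
    period_s: float = 5.0

    def __post_init__(self) -> None:
        if self.amplitude_deg <= 0:
            raise ParameterError("serpentine amplitude must be > 0")


@dataclass
class GroundTruth:
    """Exhaustive per-record truth for one generated artifact."""

    clock_offset_s: float = 0.0
    fault_labels: Optional[np.ndarray] = None  # bool per GPS fix
    fault_indices: list = field(default_factory=list)
    true_lat: Optional[np.ndarray] = None
    true_lon: Optional[np.ndarray] = None
    phases: dict = field(default_factory=dict)  # true clock
    initial_heading_deg: float = float("nan")
    final_heading_deg: float = float("nan")
    frames: Optional[pd.DataFrame] = None  # gaze validation truth
    trials: Optional[pd.DataFrame] = None  # pointing truth

    def to_dict(self) -> dict:
        out = {
            "clock_offset_s": self.clock_offset_s,
            "fault_indices": [int(i) for i in self.fault_indices],
            "phases": {k: list(v) for k, v in self.phases.items()},
            "initial_heading_deg": self.initial_heading_deg,
            "final_heading_deg": self.final_heading_deg,
        }
        if self.frames is not None:
            out["frames"] = self.frames.to_dict(orient="records")
        if self.trials is not None:
            out["trials"] = self.trials.to_dict(orient="records")
        return out


# --- shared kinematics ------------------------------------------------------

def _kinematics(scenario: WalkScenario, serpentine: SerpentineSpec):
    """Per-GPS-sample true time, heading (cardinal) and speed (km/h).

    Both the GPS and the IMU generator derive from this single series, so
    the two streams describe the same physical walk.
    """
    rng = _rng(scenario.seed, 0)
    dt = 1.0 / scenario.gps_rate_hz
    t = np.arange(0.0, scenario.total_duration_s + dt / 2, dt)
    n = t.size
    heading = np.full(n, scenario.initial_heading_deg, dtype=float)
    speed = np.zeros(n)
    ph = scenario.phases
    mean, sd = scenario.mean_speed_kmh, scenario.speed_sd_kmh
    phi = scenario.speed_ar1
    v = mean
    h_walk = scenario.initial_heading_deg
    for i, ti in enumerate(t):
        if ti < ph["calibration"][1]:
            speed[i] = 0.0
            heading[i] = scenario.initial_heading_deg
        elif ti < ph["serpentine"][1]:
            speed[i] = mean
            tau = ti - ph["serpentine"][0]
            heading[i] = scenario.initial_heading_deg + serpentine.amplitude_deg * np.sin(
                2.0 * np.pi * tau / serpentine.period_s
            )
        elif ti < ph["walk"][1]:
            v = mean + phi * (v - mean) + rng.normal(0.0, sd * np.sqrt(max(1.0 - phi**2, 0.0)))
            v = float(np.clip(v, mean - 2.0 * sd, mean + 2.0 * sd))
            speed[i] = v
            h_walk = h_walk + rng.normal(0.0, scenario.heading_step_sd_deg * np.sqrt(dt))
            heading[i] = h_walk
        else:
            speed[i] = 0.0
            heading[i] = h_walk
    return t, heading, speed


def _integrate_positions(scenario: WalkScenario, t, heading_deg, speed_kmh):
    """Local ENU integration re-projected to WGS84 (planar approximation).

    Zero-order hold: heading[i] and speed[i] apply to the segment
    t[i] → t[i+1], so the implied course over ground of segment i is
    exactly heading[i]."""
    dt = np.diff(t)
    v_ms = np.asarray(speed_kmh) / 3.6
    h = np.radians(heading_deg)
    x = np.concatenate([[0.0], np.cumsum(v_ms[:-1] * dt * np.sin(h[:-1]))])  # east
    y = np.concatenate([[0.0], np.cumsum(v_ms[:-1] * dt * np.cos(h[:-1]))])  # north
    lat0, lon0 = scenario.origin
    lat = lat0 + np.degrees(y / EARTH_RADIUS_M)
    lon = lon0 + np.degrees(x / (EARTH_RADIUS_M * np.cos(np.radians(lat0))))
    return lat, lon


# --- generators -------------------------------------------------------------

def simulate_walk_track(
    scenario: WalkScenario,
    serpentine: SerpentineSpec | None = None,
) -> tuple[GeoTrack, GroundTruth]:
    """Simulate the GPS stream of one session with injected faults.

    Returns the track (timestamps on the *GPS* clock, i.e. true time minus
    the scenario clock offset) and exhaustive ground truth (true positions,
    one fault label per fix, the true offset and the phase boundaries).
    """
    serpentine = serpentine or SerpentineSpec()
    t, heading, speed = _kinematics(scenario, serpentine)
    lat, lon = _integrate_positions(scenario, t, heading, speed)
    n = t.size

    jitter = _rng(scenario.seed, 1)
    m_per_deg_lat = EARTH_RADIUS_M * np.pi / 180.0
    m_per_deg_lon = m_per_deg_lat * np.cos(np.radians(scenario.origin[0]))
    obs_lat = lat + jitter.normal(0.0, scenario.position_jitter_m, n) / m_per_deg_lat
    obs_lon = lon + jitter.normal(0.0, scenario.position_jitter_m, n) / m_per_deg_lon

    quality = np.full(n, scenario.clean_quality, dtype=float)
    sats = np.full(n, scenario.clean_satellites, dtype=float)
    labels = np.zeros(n, dtype=bool)
    fault_rng = _rng(scenario.seed, 3)
    for fs in scenario.faults:
        i = int(np.argmin(np.abs(t - fs.time_s)))
        labels[i] = True
        if fs.displacement_m:
            ang = fault_rng.uniform(0.0, 2.0 * np.pi)
            obs_lat[i] += fs.displacement_m * np.cos(ang) / m_per_deg_lat
            obs_lon[i] += fs.displacement_m * np.sin(ang) / m_per_deg_lon
        if fs.quality is not None:
            quality[i] = fs.quality
        if fs.n_satellites is not None:
            sats[i] = fs.n_satellites

    track = GeoTrack(
        pd.DataFrame(
            {
                "t": t - scenario.clock_offset_s,
                "lat": obs_lat,
                "lon": obs_lon,
                "quality": quality,
                "n_satellites": sats,
                "precision": np.nan,
            }
        ),
        source="rtk",
    )
    truth = GroundTruth(
        clock_offset_s=scenario.clock_offset_s,
        fault_labels=labels,
        fault_indices=list(np.flatnonzero(labels)),
        true_lat=lat,
        true_lon=lon,
        phases=scenario.phases,
        initial_heading_deg=float(wrap_cardinal(scenario.initial_heading_deg)),
        final_heading_deg=float(wrap_cardinal(heading[-1])),
    )
    return track, truth


def simulate_camera_track(
    scenario: WalkScenario,
    precision_m: float = 2.0,
    precision_sd_m: float = 0.3,
    serpentine: SerpentineSpec | None = None,
) -> tuple[GeoTrack, GroundTruth]:
    """Action-camera variant: same walk, precision column instead of
    quality/satellites; faulted fixes get an inflated precision."""
    track, truth = simulate_walk_track(scenario, serpentine)
    rng = _rng(scenario.seed, 4)
    n = len(track)
    prec = np.abs(rng.normal(precision_m, precision_sd_m, n))
    prec[truth.fault_labels] += 30.0 * precision_m
    data = track.data.copy()
    data["quality"] = np.nan
    data["n_satellites"] = np.nan
    data["precision"] = prec
    return GeoTrack(data, source="camera"), truth


def simulate_imu_trace(
    scenario: WalkScenario,
    serpentine: SerpentineSpec | None = None,
    rate_hz: float = 110.0,
    yaw_noise_sd_deg: float = 1.0,
) -> tuple[ImuTrace, GroundTruth]:
    """Simulate the head-tracker yaw stream of the same session.

    Timestamps are on the IMU (reference) clock. The trace starts with a
    stationary hold at the initial heading (the window the heading
    validation reads), performs three 360° yaw rotations during the
    calibration phase, oscillates during the serpentine bout, then follows
    the walk heading; ends with a stationary tail for the end validation.
    """
    serpentine = serpentine or SerpentineSpec()
    t_kin, heading, _ = _kinematics(scenario, serpentine)
    dt = 1.0 / rate_hz
    t = np.arange(0.0, scenario.total_duration_s, dt)
    # continuous heading: linear interpolation of the (unwrapped) kinematic series
    heading_cont = np.interp(t, t_kin, np.degrees(np.unwrap(np.radians(heading))))
    ph = scenario.phases
    cal0, cal1 = ph["calibration"]
    in_cal = (t >= cal0) & (t < cal1)
    # three full 360° yaw rotations across the calibration window
    tau = (t[in_cal] - cal0) / (cal1 - cal0)
    heading_cont[in_cal] = scenario.initial_heading_deg + 3.0 * 360.0 * tau
    rng = _rng(scenario.seed, 2)
    yaw = wrap_signed(heading_cont + rng.normal(0.0, yaw_noise_sd_deg, t.size))
    trace = ImuTrace(pd.DataFrame({"t": t, "yaw": yaw}), nominal_rate_hz=rate_hz)
    truth = GroundTruth(
        clock_offset_s=scenario.clock_offset_s,
        phases=ph,
        initial_heading_deg=float(wrap_cardinal(scenario.initial_heading_deg)),
        final_heading_deg=float(wrap_cardinal(heading[-1])),
    )
    return trace, truth


def grid_target_centers(
    n_targets: int,
    frame_size: tuple[int, int] = (1600, 1200),
    margin_px: float = 200.0,
) -> np.ndarray:
    """Default placement of validation targets: a centered grid."""
    if n_targets < 1:
        raise ParameterError("n_targets must be >= 1")
    ncols = int(np.ceil(np.sqrt(n_targets * frame_size[0] / frame_size[1])))
    nrows = int(np.ceil(n_targets / ncols))
    xs = np.linspace(margin_px, frame_size[0] - margin_px, ncols)
    ys = np.linspace(margin_px, frame_size[1] - margin_px, nrows)
    centers = [(x, y) for y in ys for x in xs]
    return np.array(centers[:n_targets])


def simulate_validation_scene(
    n_targets: int = 10,
    frames_per_target: int = 5,
    noise_sd_px: float = 15.0,
    seed: int = 0,
    samples_per_frame: int = 7,
    frame_rate_hz: float = 30.0,
    frame_size: tuple[int, int] = (1600, 1200),
    box_px: float = 28.0,
    recording_id: str = "synthetic",
    target_centers: Optional[np.ndarray] = None,
) -> tuple[ValidationScene, GroundTruth]:
    """Simulate one 10-target gaze validation with known gaze noise.

    Per annotated frame, ``samples_per_frame`` gaze samples are drawn so
    that their mean is the target center plus isotropic Gaussian noise of
    sd ``noise_sd_px`` (per-sample sd is scaled by √samples_per_frame).
    Ground truth records the realized per-frame mean offsets.
    """
    if noise_sd_px < 0:
        raise ParameterError("noise_sd_px must be >= 0")
    centers = (
        np.asarray(target_centers, dtype=float)
        if target_centers is not None
        else grid_target_centers(n_targets, frame_size)
    )
    rng = np.random.default_rng([int(seed), 10])
    gaze_rows = []
    ann_rows = []
    truth_rows = []
    sample_sd = noise_sd_px * np.sqrt(samples_per_frame)
    for ti in range(1, n_targets + 1):
        cx, cy = centers[ti - 1]
        for j in range(frames_per_target):
            f = (ti - 1) * frames_per_target + j
            t0 = f / frame_rate_hz
            ts = t0 + (np.arange(samples_per_frame) + 0.5) / (frame_rate_hz * samples_per_frame)
            sx = cx + rng.normal(0.0, sample_sd, samples_per_frame)
            sy = cy + rng.normal(0.0, sample_sd, samples_per_frame)
            for k in range(samples_per_frame):
                gaze_rows.append({"t": ts[k], "x": sx[k], "y": sy[k]})
            ann_rows.append(
                {
                    "recording_id": recording_id,
                    "target": ti,
                    "frame": f,
                    "x": cx - box_px / 2.0,
                    "y": cy - box_px / 2.0,
                    "w": box_px,
                    "h": box_px,
                }
            )
            mx, my = sx.mean(), sy.mean()
            truth_rows.append(
                {
                    "target": ti,
                    "frame": f,
                    "true_cx": cx,
                    "true_cy": cy,
                    "gaze_x": mx,
                    "gaze_y": my,
                    "offset_px": float(np.hypot(mx - cx, my - cy)),
                }
            )
    scene = ValidationScene(
        gaze=pd.DataFrame(gaze_rows),
        annotations=pd.DataFrame(ann_rows),
        recording_id=recording_id,
        frame_rate_hz=frame_rate_hz,
        frame_size=frame_size,
    )
    return scene, GroundTruth(frames=pd.DataFrame(truth_rows))


@dataclass(frozen=True)
class LinearConfidence:
    """Monotone link |error| → confidence: 10·max(0, 1 − |e|/scale), rounded."""

    scale_deg: float = 90.0

    def __call__(self, abs_error_deg: float) -> int:
        return int(round(10.0 * max(0.0, 1.0 - abs_error_deg / self.scale_deg)))


def simulate_pointing_session(
    location: tuple[float, float],
    targets: dict,
    angular_noise_sd_deg: float = 10.0,
    declination_deg: float = 0.0,
    confidence_model: Optional[Callable[[float], int]] = None,
    seed: int = 0,
    n_repeats: int = 1,
    include_north: bool = True,
) -> tuple[list[PointingTrial], GroundTruth]:
    """Simulate pointing trials at one location with known angular noise.

    Per repeat, one north trial (if requested) plus one trial per building
    in a seed-randomized order. The compass reading is the true bearing
    minus the declination plus wrapped-Gaussian noise — i.e. what a magnetic
    compass would show; ground truth stores the true bearings and the true
    signed errors.
    """
    if not targets and not include_north:
        raise ParameterError("need at least one target or the north trial")
    if angular_noise_sd_deg < 0:
        raise ParameterError("angular_noise_sd_deg must be >= 0")
    from .pointing_tasks import true_bearing

    rng = np.random.default_rng([int(seed), 20])
    lat1, lon1 = location
    trials: list[PointingTrial] = []
    truth_rows = []
    for rep in range(n_repeats):
        keys = list(targets)
        order = ["north"] * int(include_north) + [str(k) for k in keys]
        building_part = order[int(include_north):]
        rng.shuffle(building_part)
        order = order[: int(include_north)] + building_part
        for pos, key in enumerate(order):
            if key == "north":
                bearing = 0.0
                task = "north"
                lat2 = lon2 = None
                target_id = None
            else:
                task = "building"
                lat2, lon2 = targets[key]
                bearing = true_bearing(lat1, lon1, lat2, lon2)
                target_id = key
            noise = float(wrap_signed(rng.normal(0.0, angular_noise_sd_deg)))
            reading = float(wrap_cardinal(bearing - declination_deg + noise))
            conf = confidence_model(abs(noise)) if confidence_model else None
            trial_id = f"r{rep}_{pos}_{key}"
            trials.append(
                PointingTrial(
                    trial_id=trial_id,
                    task=task,
                    lat1=lat1,
                    lon1=lon1,
                    lat2=lat2,
                    lon2=lon2,
                    target_id=target_id,
                    compass_reading_deg=reading,
                    declination_deg=declination_deg,
                    confidence=conf,
                )
            )
            truth_rows.append(
                {
                    "trial_id": trial_id,
                    "task": task,
                    "target_id": target_id,
                    "true_bearing_deg": float(wrap_cardinal(bearing)),
                    "true_signed_error_deg": noise,
                }
            )
    return trials, GroundTruth(trials=pd.DataFrame(truth_rows))


# --- full session materialization -------------------------------------------

def write_synthetic_session(
    out_dir,
    scenario: WalkScenario | None = None,
    serpentine: SerpentineSpec | None = None,
    noise_sd_px: float = 15.0,
    angular_noise_sd_deg: float = 10.0,
    pointing_targets: Optional[dict] = None,
    declination_deg: float = 3.9,
    compass_error_sd_deg: float = 1.0,
    session_id: str = "1_1",
) -> Path:
    """Materialize a full synthetic session directory (CSV + manifest + truth).

    Returns the manifest path; the directory is directly consumable by
    ``fieldgaze run``.
    """
    scenario = scenario or WalkScenario()
    serpentine = serpentine or SerpentineSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    track, gps_truth = simulate_walk_track(scenario, serpentine)
    trace, imu_truth = simulate_imu_trace(scenario, serpentine)
    recordings_io.write_gps_table(track, out_dir / "gps.csv")
    recordings_io.write_imu_table(trace, out_dir / "imu.csv")

    seed = scenario.seed
    scene_start, truth_start = simulate_validation_scene(
        noise_sd_px=noise_sd_px, seed=seed, recording_id=f"{session_id}_start"
    )
    scene_end, truth_end = simulate_validation_scene(
        noise_sd_px=noise_sd_px, seed=seed + 1, recording_id=f"{session_id}_end"
    )
    recordings_io.write_gaze_table(scene_start.gaze, out_dir / "gaze_start.csv")
    recordings_io.write_validation_annotations(
        scene_start.annotations, out_dir / "annotations_start.csv"
    )
    recordings_io.write_gaze_table(scene_end.gaze, out_dir / "gaze_end.csv")
    recordings_io.write_validation_annotations(
        scene_end.annotations, out_dir / "annotations_end.csv"
    )

    comp_rng = np.random.default_rng([int(seed), 30])
    readings = [
        CompassReading(
            session_id,
            "start",
            float(
                wrap_cardinal(
                    gps_truth.initial_heading_deg
                    + comp_rng.normal(0.0, compass_error_sd_deg)
                )
            ),
        ),
        CompassReading(
            session_id,
            "end",
            float(
                wrap_cardinal(
                    gps_truth.final_heading_deg
                    + comp_rng.normal(0.0, compass_error_sd_deg)
                )
            ),
        ),
    ]
    recordings_io.write_compass_readings(readings, out_dir / "compass.csv")

    lat0, lon0 = scenario.origin
    if pointing_targets is None:
        pointing_targets = {
            str(i + 1): (lat0 + 0.004 * np.cos(a), lon0 + 0.004 * np.sin(a))
            for i, a in enumerate(np.linspace(0.2, 2 * np.pi, 8, endpoint=False))
        }
    trials, point_truth = simulate_pointing_session(
        (lat0, lon0),
        pointing_targets,
        angular_noise_sd_deg=angular_noise_sd_deg,
        declination_deg=declination_deg,
        confidence_model=LinearConfidence(),
        seed=seed,
        n_repeats=3,
    )
    recordings_io.write_pointing_table(trials, out_dir / "pointing.csv")

    ph = scenario.phases
    manifest = SessionManifest(
        session_id=session_id,
        planned_duration_min=scenario.duration_s / 60.0,
        declination_deg=declination_deg,
        streams={
            "gps": out_dir / "gps.csv",
            "imu": out_dir / "imu.csv",
            "gaze_start": out_dir / "gaze_start.csv",
            "annotations_start": out_dir / "annotations_start.csv",
            "gaze_end": out_dir / "gaze_end.csv",
            "annotations_end": out_dir / "annotations_end.csv",
            "compass": out_dir / "compass.csv",
            "pointing": out_dir / "pointing.csv",
        },
        gps_source="rtk",
        anchors={
            "gps_anchor_s": ph["serpentine"][0] - scenario.clock_offset_s,
            "imu_anchor_s": ph["serpentine"][0],
        },
        exploration_window_s=ph["walk"],
        end_validation_anchor_s=ph["tail"][0],
        pointing_location=(lat0, lon0),
        pointing_targets=pointing_targets,
    )
    manifest_path = out_dir / "manifest.yaml"
    recordings_io.save_manifest(manifest, manifest_path)

    recordings_io.write_json(
        {
            "gps": gps_truth.to_dict(),
            "imu": imu_truth.to_dict(),
            "validation_start": truth_start.to_dict(),
            "validation_end": truth_end.to_dict(),
            "pointing": point_truth.to_dict(),
        },
        out_dir / "ground_truth.json",
    )
    return manifest_path
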