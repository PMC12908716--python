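"""End-to-end session orchestration and the QC report.

Stage order per session: read → align → clean → validate (gaze, heading) →
summarize → score. Absent streams skip their stages with a logged reason;
a stage failure aborts only that session and is recorded in the report so
sibling sessions still complete. The report is written atomically and
validates against the JSON schema shipped with the package.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np

from . import gaze_validation, gps_processing, heading_validation, recordings_io
from .errors import FieldgazeError, FormatError
from .pointing_tasks import aggregate_scores, confidence_correlation, score_trials
from .records import SessionManifest, ValidationScene
from .stream_alignment import (
    apply_offset,
    estimate_offset_correlation,
    offset_from_anchors,
)

log = logging.getLogger("fieldgaze.pipeline")

REPORT_VERSION = 1


@dataclass
class QCReport:
    """Structured quality-control report over one or more sessions."""

    sessions: list = field(default_factory=list)  # one dict per session
    protocol: dict = field(default_factory=dict)
    version: int = REPORT_VERSION

    def to_dict(self) -> dict:
        return {"version": self.version, "protocol": self.protocol, "sessions": self.sessions}

    @classmethod
    def from_dict(cls, d: dict) -> "QCReport":
        return cls(sessions=list(d.get("sessions", [])),
                   protocol=dict(d.get("protocol", {})),
                   version=int(d.get("version", REPORT_VERSION)))


def write_report(report: QCReport, path) -> None:
    """Write the QC report as JSON (atomic; round-trips via read_report)."""
    recordings_io.write_json(report.to_dict(), path)


def read_report(path) -> QCReport:
    return QCReport.from_dict(recordings_io.read_json(path))


def load_report_schema() -> dict:
    ref = importlib.resources.files("fieldgaze") / "data" / "qc_report.schema.json"
    import json

    return json.loads(ref.read_text(encoding="utf-8"))


def _check_schema(obj, schema, path="$") -> list:
    """Minimal structural validator for the shipped report schema
    (type / required / properties / items subset of JSON Schema)."""
    problems = []
    typemap = {
        "object": dict, "array": list, "string": str,
        "number": (int, float), "integer": int, "boolean": bool,
    }
    expected = schema.get("type")
    if expected and not isinstance(obj, typemap[expected]):
        problems.append(f"{path}: expected {expected}, got {type(obj).__name__}")
        return problems
    if expected == "object":
        for key in schema.get("required", []):
            if key not in obj:
                problems.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                problems.extend(_check_schema(obj[key], sub, f"{path}.{key}"))
    elif expected == "array" and "items" in schema:
        for i, item in enumerate(obj):
            problems.extend(_check_schema(item, schema["items"], f"{path}[{i}]"))
    return problems


def validate_report(report: QCReport) -> None:
    """Raise FormatError if the report violates the shipped schema."""
    problems = _check_schema(report.to_dict(), load_report_schema())
    if problems:
        raise FormatError("QC report schema violations: " + "; ".join(problems))


# --- stages -----------------------------------------------------------------

def _gaze_block(manifest: SessionManifest) -> dict | None:
    streams = manifest.streams
    phases = {}
    audits = {}
    for phase in ("start", "end"):
        gaze_p = streams.get(f"gaze_{phase}") or (streams.get("gaze") if phase == "start" else None)
        ann_p = streams.get(f"annotations_{phase}") or (
            streams.get("annotations") if phase == "start" else None
        )
        if gaze_p is None or ann_p is None:
            continue
        scene = ValidationScene(
            gaze=recordings_io.read_gaze_table(gaze_p),
            annotations=recordings_io.read_validation_annotations(ann_p),
            recording_id=f"{manifest.session_id}_{phase}",
            target_size_cm=manifest.target_diameter_cm,
            viewing_distance_cm=manifest.viewing_distance_cm,
        )
        result = gaze_validation.summarize_validation(scene, phase=phase)
        phases[phase] = result.to_dict()
        audits[phase] = result.frames
    if not phases:
        return None
    return {"phases": phases, "n_frame_errors": int(sum(len(a) for a in audits.values()))}


def _heading_block(manifest: SessionManifest) -> dict | None:
    streams = manifest.streams
    if not streams.get("imu") or not streams.get("compass"):
        return None
    trace = recordings_io.read_imu_table(streams["imu"])
    readings = recordings_io.read_compass_readings(streams["compass"])
    out = {}
    for reading in readings:
        anchor = None if reading.phase == "start" else manifest.end_validation_anchor_s
        if reading.phase == "end" and anchor is None:
            log.info("%s: no end-validation anchor; skipping end heading", manifest.session_id)
            continue
        hv = heading_validation.validate_heading(
            trace, reading.heading_deg, manifest.session_id,
            phase=reading.phase, anchor_t=anchor,
        )
        out[reading.phase] = {
            "imu_heading_deg": hv.imu_heading_deg,
            "compass_heading_deg": hv.compass_heading_deg,
            "signed_error_deg": hv.signed_error_deg,
            "n_samples": hv.n_samples,
        }
    return out or None


def _gps_blocks(manifest: SessionManifest) -> tuple[dict | None, dict | None, dict | None]:
    streams = manifest.streams
    if not streams.get("gps"):
        return None, None, None
    path = streams["gps"]
    if str(path).endswith(".gpx"):
        track = recordings_io.read_gpx_track(path)
    else:
        track = recordings_io.read_gps_table(path, source=manifest.gps_source)

    alignment = None
    if manifest.anchors.get("gps_anchor_s") is not None and manifest.anchors.get("imu_anchor_s") is not None:
        result = offset_from_anchors(
            manifest.anchors["gps_anchor_s"], manifest.anchors["imu_anchor_s"]
        )
        track = apply_offset(track, result)
        alignment = result.to_dict()
    elif streams.get("imu"):
        trace = recordings_io.read_imu_table(streams["imu"])
        result = estimate_offset_correlation(track, trace)
        track = apply_offset(track, result)
        alignment = result.to_dict()

    if manifest.exploration_window_s is not None:
        track = track.crop(*manifest.exploration_window_s)

    if manifest.gps_source == "camera":
        report = gps_processing.flag_outliers_camera(track)
    else:
        report = gps_processing.flag_outliers_rtk(track)
    cleaned = gps_processing.clean_track(track, report)
    movement = gps_processing.track_summary(cleaned)
    return alignment, report.to_dict(), movement


def _pointing_block(manifest: SessionManifest) -> dict | None:
    streams = manifest.streams
    if not streams.get("pointing") or manifest.pointing_location is None:
        return None
    trials = recordings_io.read_pointing_table(
        streams["pointing"],
        manifest.pointing_location,
        manifest.pointing_targets,
        declination_deg=manifest.declination_deg,
    )
    scores = score_trials(trials)
    by_task = aggregate_scores(scores, group_by="task")
    by_target = aggregate_scores(scores, group_by="target")
    block = {
        "n_trials": len(scores),
        "by_task": by_task.to_dict(orient="records"),
        "by_target": by_target.to_dict(orient="records"),
    }
    per_building = by_target[by_target["target"] != "north"]
    try:
        corr = confidence_correlation(per_building)
        block["confidence_correlation"] = {
            "rho": corr.statistic, "p": corr.pvalue, "n": corr.n, "method": corr.method,
        }
    except FieldgazeError as exc:
        block["confidence_correlation"] = {"error": str(exc)}
    return block


def run_pipeline(manifest: SessionManifest) -> dict:
    """Run all stages for one session; returns the session's report block."""
    block: dict = {"session_id": manifest.session_id,
                   "planned_duration_min": manifest.planned_duration_min,
                   "errors": []}
    stages = (
        ("alignment_cleaning_movement", lambda: block.update(
            zip(("alignment", "cleaning", "movement"), _gps_blocks(manifest)))),
        ("gaze_validation", lambda: block.__setitem__("gaze_validation", _gaze_block(manifest))),
        ("heading_validation", lambda: block.__setitem__("heading_validation", _heading_block(manifest))),
        ("pointing", lambda: block.__setitem__("pointing", _pointing_block(manifest))),
    )
    for name, stage in stages:
        try:
            stage()
        except (FieldgazeError, FileNotFoundError, KeyError, ValueError) as exc:
            log.error("session %s stage %s failed: %s", manifest.session_id, name, exc)
            block["errors"].append({"stage": name, "error": str(exc)})
    block = {k: v for k, v in block.items() if v is not None}
    return block


def run_sessions(manifests) -> QCReport:
    """Run the pipeline over several sessions; failures stay per-session."""
    report = QCReport()
    for manifest in manifests:
        report.sessions.append(run_pipeline(manifest))
    report.protocol = summarize_protocol(manifests)
    return report


def summarize_protocol(manifests) -> dict:
    """Planned-duration totals of a set of session manifests."""
    sessions = [
        {"session_id": m.session_id, "planned_duration_min": float(m.planned_duration_min)}
        for m in manifests
    ]
    return {
        "n_sessions": len(sessions),
        "sessions": sessions,
        "total_planned_min": float(np.sum([s["planned_duration_min"] for s in sessions]))
        if sessions
        else 0.0,
    }


def load_session_plan() -> list[SessionManifest]:
    """The packaged study session plan (five sessions over three days)."""
    import json

    ref = importlib.resources.files("fieldgaze") / "data" / "session_plan.json"
    plan = json.loads(ref.read_text(encoding="utf-8"))
    return [
        SessionManifest(
            session_id=s["session_id"],
            planned_duration_min=s["planned_duration_min"],
        )
        for s in plan["sessions"]
    ]
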