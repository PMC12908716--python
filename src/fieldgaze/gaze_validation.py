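"""Gaze-accuracy validation against handheld targets.

During the field protocol the participant fixates 10 handheld circular
targets (12 cm diameter) at a 3 m viewing distance before and after each
recording segment. For each target a 1-second stable fixation window is
annotated, five evenly spaced video frames are extracted, and the gaze
samples falling inside each frame's exposure interval are averaged to a
single gaze point. The per-frame accuracy error is then computed in three
steps:

1. pixel offset — Euclidean distance between mean gaze and target-box
   center in scene-camera pixels;
2. centimeter offset — pixel offset scaled by the known physical target
   diameter over its pixel diameter;
3. visual angle — θ = 2·arctan(offset_cm / (2·viewing_distance_cm)).

Session-level accuracy is the median over the 10 per-target medians of the
per-frame angles. Start-vs-end stability is assessed with an exact Wilcoxon
signed-rank test on the paired session medians.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, EmptyInputError, ParameterError
from .exact_stats import TestResult, wilcoxon_signed_rank
from .records import ValidationScene

log = logging.getLogger("fieldgaze.gaze")


def pixel_offset(x_gaze, y_gaze, x_target, y_target):
    """Euclidean gaze-to-target offset in pixels (vectorized)."""
    return np.hypot(
        np.asarray(x_gaze, dtype=float) - np.asarray(x_target, dtype=float),
        np.asarray(y_gaze, dtype=float) - np.asarray(y_target, dtype=float),
    )


def offset_to_cm(offset_px, target_size_cm: float, target_size_px: float):
    """Convert a pixel offset to centimeters via the physical target size."""
    if np.any(np.asarray(target_size_px, dtype=float) <= 0):
        raise ParameterError("target_size_px must be > 0")
    return np.asarray(offset_px, dtype=float) * target_size_cm / target_size_px


def offset_to_deg(offset_cm, viewing_distance_cm: float):
    """Convert a centimeter offset to degrees of visual angle."""
    if viewing_distance_cm <= 0:
        raise ParameterError("viewing_distance_cm must be > 0")
    offset_cm = np.asarray(offset_cm, dtype=float)
    if np.any(offset_cm < 0):
        raise ParameterError("offset_cm must be >= 0")
    return np.degrees(2.0 * np.arctan(offset_cm / (2.0 * viewing_distance_cm)))


def visual_angle_error(
    x_gaze, y_gaze, x_target, y_target,
    target_size_px, target_size_cm: float = 12.0,
    viewing_distance_cm: float = 300.0,
):
    """Full pixel → cm → visual-angle chain for one or many frames."""
    off_px = pixel_offset(x_gaze, y_gaze, x_target, y_target)
    off_cm = offset_to_cm(off_px, target_size_cm, target_size_px)
    return off_px, off_cm, offset_to_deg(off_cm, viewing_distance_cm)


def select_frames(frame_ids, k: int = 5) -> list:
    """k evenly spaced frames across a window, endpoints included.

    Spacing uses round-half-up on the fractional index; a window of at most
    k frames is returned whole.
    """
    frame_ids = list(frame_ids)
    n = len(frame_ids)
    if n == 0:
        raise EmptyInputError("empty frame window")
    if k < 1:
        raise ParameterError("k must be >= 1")
    if n <= k:
        return frame_ids
    idx = [math.floor(i * (n - 1) / (k - 1) + 0.5) for i in range(k)]
    return [frame_ids[i] for i in idx]


@dataclass
class ValidationResult:
    """Per-frame, per-target, and session-level gaze errors for one scene."""

    recording_id: str
    phase: str  # "start" | "end"
    frames: pd.DataFrame  # target, frame, n_samples, offset_px, offset_cm, theta_deg
    target_medians_deg: pd.Series  # indexed by target
    session_median_deg: float
    iqr_across_targets: tuple[float, float] = (float("nan"), float("nan"))
    iqr_across_frames: tuple[float, float] = (float("nan"), float("nan"))
    skipped_frames: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "recording_id": self.recording_id,
            "phase": self.phase,
            "n_frames": int(len(self.frames)),
            "target_medians_deg": {
                str(k): float(v) for k, v in self.target_medians_deg.items()
            },
            "session_median_deg": float(self.session_median_deg),
            "iqr_across_targets_deg": [float(q) for q in self.iqr_across_targets],
            "iqr_across_frames_deg": [float(q) for q in self.iqr_across_frames],
        }


def summarize_validation(scene: ValidationScene, phase: str = "start") -> ValidationResult:
    """Compute frame / target / session gaze errors for one validation scene.

    Per frame, the gaze point is the arithmetic mean of all gaze samples in
    the frame's half-open exposure interval; frames without gaze samples are
    skipped with a log entry, and a target left with no frames raises
    :class:`CoverageError`. All frame-level errors are retained for audit.
    """
    ann = scene.annotations
    if len(ann) == 0:
        raise EmptyInputError("scene has no annotations")
    fps = scene.frame_rate_hz
    gaze_t = scene.gaze["t"].to_numpy(dtype=float)
    gaze_x = scene.gaze["x"].to_numpy(dtype=float)
    gaze_y = scene.gaze["y"].to_numpy(dtype=float)

    rows = []
    skipped = []
    for r in ann.itertuples():
        f = int(r.frame)
        t0, t1 = f / fps, (f + 1) / fps
        in_frame = (gaze_t >= t0) & (gaze_t < t1)
        n = int(in_frame.sum())
        if n == 0:
            skipped.append((int(r.target), f))
            continue
        gx, gy = gaze_x[in_frame].mean(), gaze_y[in_frame].mean()
        cx = r.x + r.w / 2.0
        cy = r.y + r.h / 2.0
        size_px = float(max(r.w, r.h))
        off_px, off_cm, theta = visual_angle_error(
            gx, gy, cx, cy, size_px,
            scene.target_size_cm, scene.viewing_distance_cm,
        )
        rows.append(
            {
                "target": int(r.target),
                "frame": f,
                "n_samples": n,
                "offset_px": float(off_px),
                "offset_cm": float(off_cm),
                "theta_deg": float(theta),
            }
        )
    if skipped:
        log.warning(
            "%s: skipped %d annotated frame(s) without gaze samples",
            scene.recording_id, len(skipped),
        )
    frames = pd.DataFrame(rows)
    for target in sorted(ann["target"].unique()):
        if len(frames) == 0 or int(target) not in set(frames["target"]):
            raise CoverageError(f"target {int(target)} has no usable frames")
    target_medians = frames.groupby("target")["theta_deg"].median()
    session_median = float(target_medians.median())
    q_t = np.percentile(target_medians.to_numpy(), [25, 75])
    q_f = np.percentile(frames["theta_deg"].to_numpy(), [25, 75])
    return ValidationResult(
        recording_id=scene.recording_id,
        phase=phase,
        frames=frames,
        target_medians_deg=target_medians,
        session_median_deg=session_median,
        iqr_across_targets=(float(q_t[0]), float(q_t[1])),
        iqr_across_frames=(float(q_f[0]), float(q_f[1])),
        skipped_frames=skipped,
    )


def compare_start_end(pairs) -> TestResult:
    """Wilcoxon signed-rank test on paired (start, end) session medians.

    ``pairs`` maps session id -> (start, end); sessions missing either phase
    (None/NaN) are excluded with a log entry. Differences are end − start.
    """
    diffs = []
    for sid, (start, end) in dict(pairs).items():
        if start is None or end is None or not np.isfinite([start, end]).all():
            log.info("session %s excluded from start/end comparison (missing phase)", sid)
            continue
        diffs.append(end - start)
    if not diffs:
        raise EmptyInputError("no complete start/end pairs")
    return wilcoxon_signed_rank(diffs)
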