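"""IMU heading validation against compass photo read-outs.

At every segment boundary the head tracker is aligned with a reference
compass and a photo of the compass face is taken. Offline, a short
magnetometer window — 0.5 s, i.e. 55 samples at the tracker's 110 Hz — is
reduced to a circular median heading and compared with the compass value.
The start window is the first 55 samples of the recording; the end window
is the first 55 samples after the analyst-supplied anchor where the tracker
is placed back on the reference device. Errors are signed shortest-arc
differences in (−180, 180].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .circular import circ_diff, circular_median, wrap_cardinal
from .errors import CoverageError, RangeError
from .exact_stats import TestResult, wilcoxon_signed_rank
from .records import ImuTrace

log = logging.getLogger("fieldgaze.heading")

#: Validation window: 0.5 s of magnetometer data at the nominal 110 Hz.
WINDOW_SECONDS = 0.5
WINDOW_SAMPLES = 55


@dataclass(frozen=True)
class HeadingValidation:
    """One IMU-vs-compass comparison at a segment boundary."""

    session_id: str
    phase: str  # "start" | "end"
    imu_heading_deg: float  # cardinal
    compass_heading_deg: float  # cardinal
    n_samples: int

    @property
    def signed_error_deg(self) -> float:
        return float(circ_diff(self.imu_heading_deg, self.compass_heading_deg))


def to_cardinal(yaw_deg):
    """Map the tracker's signed yaw output (−180, 180] to cardinal [0, 360)."""
    yaw = np.asarray(yaw_deg, dtype=float)
    if np.any((yaw <= -180.0) | (yaw > 180.0)):
        raise RangeError("yaw outside (-180, 180]")
    return wrap_cardinal(yaw)


def imu_window_heading(
    trace: ImuTrace,
    anchor_t: float,
    n_samples: int = WINDOW_SAMPLES,
) -> tuple[float, int]:
    """Circular-median heading of up to ``n_samples`` samples from an anchor.

    Returns ``(heading_cardinal_deg, n_used)``. The start-phase anchor is the
    recording onset (``trace.t[0]``); the end-phase anchor is the timestamp
    at which the tracker was placed on the reference device, supplied by the
    analyst.
    """
    t = trace.t
    idx = np.flatnonzero(t >= anchor_t)
    if idx.size == 0:
        raise CoverageError(f"no IMU samples at/after anchor t={anchor_t}")
    sel = idx[:n_samples]
    heading = circular_median(to_cardinal(trace.yaw[sel]))
    return heading, int(sel.size)


def heading_error(imu_heading_deg: float, compass_heading_deg: float) -> float:
    """Signed IMU-minus-compass error, wrapped into (−180, 180]."""
    if not (0.0 <= imu_heading_deg < 360.0) or not (0.0 <= compass_heading_deg < 360.0):
        raise RangeError("headings must be cardinal degrees in [0, 360)")
    return float(circ_diff(imu_heading_deg, compass_heading_deg))


def validate_heading(
    trace: ImuTrace,
    compass_heading_deg: float,
    session_id: str,
    phase: str = "start",
    anchor_t: float | None = None,
) -> HeadingValidation:
    """Compare the IMU window heading with one compass read-out."""
    if anchor_t is None:
        anchor_t = float(trace.t[0])
    imu_heading, n_used = imu_window_heading(trace, anchor_t)
    return HeadingValidation(
        session_id=session_id,
        phase=phase,
        imu_heading_deg=imu_heading,
        compass_heading_deg=compass_heading_deg,
        n_samples=n_used,
    )


def compare_start_end_headings(pairs) -> TestResult:
    """Wilcoxon signed-rank test on paired start/end signed heading errors.

    ``pairs`` maps session id -> (start_error, end_error) in signed degrees;
    sessions missing the end validation (e.g. truncated head-tracking
    recordings) are excluded with a log entry. Differences are end − start
    on the shortest arc.
    """
    diffs = []
    for sid, (start, end) in dict(pairs).items():
        if start is None or end is None or not np.isfinite([start, end]).all():
            log.info("session %s excluded from heading comparison (missing phase)", sid)
            continue
        diffs.append(float(circ_diff(end, start)))
    if not diffs:
        raise CoverageError("no complete start/end heading pairs")
    return wilcoxon_signed_rank(diffs)
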