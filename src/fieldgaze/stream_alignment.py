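"""Cross-device clock alignment between the GPS stream and the IMU stream.

The GPS logger and the eye tracker (which also records the IMU) run on
independent internal clocks that can disagree by several seconds. The IMU
clock is the reference — gaze and head tracking share a device — and the
estimated offset δ is *added to GPS timestamps* to land them on the IMU
clock.

Two estimators:

* anchors — the analyst identifies the same physical event (the serpentine
  synchronization walk, movement onset/offset) in both streams and supplies
  one timestamp per clock; δ is their difference.
* correlation — an automated fallback that slides the GPS course-over-ground
  series against the IMU yaw heading and picks the lag maximizing their
  circular agreement (mean cosine of the heading difference), on a grid at
  the GPS sample period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .circular import unwrap_deg, wrap_cardinal
from .errors import IllConditionedError, ParameterError
from .pointing_tasks import true_bearing
from .records import GeoTrack, ImuTrace


@dataclass(frozen=True)
class AlignmentResult:
    """Estimated clock offset (s) to add to GPS timestamps, plus provenance."""

    offset_s: float
    method: str  # "anchors" | "correlation"
    uncertainty_s: float = float("nan")
    anchors: Optional[tuple[float, float]] = None  # (gps_anchor, imu_anchor)
    score: float = float("nan")
    lags_s: tuple = field(default=(), compare=False)

    def to_dict(self) -> dict:
        return {
            "offset_s": self.offset_s,
            "method": self.method,
            "uncertainty_s": self.uncertainty_s,
            "anchors": list(self.anchors) if self.anchors else None,
            "score": None if np.isnan(self.score) else self.score,
        }


def offset_from_anchors(gps_anchor_s: float, imu_anchor_s: float) -> AlignmentResult:
    """δ = imu_anchor − gps_anchor for one analyst-matched event."""
    if not np.isfinite(gps_anchor_s) or not np.isfinite(imu_anchor_s):
        raise ParameterError("anchors must be finite")
    return AlignmentResult(
        offset_s=float(imu_anchor_s - gps_anchor_s),
        method="anchors",
        uncertainty_s=0.0,
        anchors=(float(gps_anchor_s), float(imu_anchor_s)),
    )


def apply_offset(track: GeoTrack, result: AlignmentResult) -> GeoTrack:
    """Shift every GPS timestamp by the estimated offset (order-preserving)."""
    data = track.data.copy()
    data["t"] = data["t"] + result.offset_s
    return GeoTrack(data, source=track.source, n_rejected=track.n_rejected)


def course_over_ground(track: GeoTrack) -> np.ndarray:
    """Per-segment bearing between consecutive fixes, cardinal degrees.

    Returns a structured pair ``(t_mid, bearing_deg)`` as a (n−1, 2) array;
    segments between coincident fixes have NaN bearing (heading undefined
    while stationary).
    """
    if len(track) < 2:
        raise ParameterError("need at least 2 fixes for course over ground")
    t, lat, lon = track.t, track.lat, track.lon
    n = len(t) - 1
    out = np.full((n, 2), np.nan)
    out[:, 0] = (t[:-1] + t[1:]) / 2.0
    for i in range(n):
        if lat[i] == lat[i + 1] and lon[i] == lon[i + 1]:
            continue
        out[i, 1] = true_bearing(lat[i], lon[i], lat[i + 1], lon[i + 1])
    return out


def estimate_offset_correlation(
    track: GeoTrack,
    trace: ImuTrace,
    search_window_s: float = 15.0,
    min_move_m: float = 0.3,
    min_overlap: int = 10,
) -> AlignmentResult:
    """Estimate δ by maximizing circular agreement of headings over lags.

    The GPS course-over-ground (only segments that actually moved at least
    ``min_move_m``) is compared against the IMU yaw heading interpolated on
    the (unwrapped) continuous heading curve; candidate lags are multiples
    of the GPS sample period within ±``search_window_s``. The uncertainty is
    one grid step.
    """
    if search_window_s <= 0:
        raise ParameterError("search_window_s must be > 0")
    from .gps_processing import haversine_m

    t, lat, lon = track.t, track.lat, track.lon
    seg_d = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    cog = course_over_ground(track)
    moving = (seg_d >= min_move_m) & np.isfinite(cog[:, 1])
    if moving.sum() < min_overlap:
        raise IllConditionedError(
            "GPS track is (nearly) motionless; use anchor-based alignment"
        )
    t_mid = cog[moving, 0]
    gps_heading = np.radians(cog[moving, 1])

    imu_t = trace.t
    imu_heading_unwrapped = unwrap_deg(wrap_cardinal(trace.yaw))

    step = float(np.median(np.diff(t)))
    k = int(np.ceil(search_window_s / step))
    lags = step * np.arange(-k, k + 1)
    scores = np.full(lags.shape, -np.inf)
    for j, lag in enumerate(lags):
        q = t_mid + lag
        ok = (q >= imu_t[0]) & (q <= imu_t[-1])
        if ok.sum() < min_overlap:
            continue
        imu_h = np.radians(np.interp(q[ok], imu_t, imu_heading_unwrapped))
        scores[j] = float(np.mean(np.cos(gps_heading[ok] - imu_h)))
    if not np.isfinite(scores).any():
        raise IllConditionedError("no lag with sufficient GPS/IMU overlap")
    best = int(np.argmax(scores))
    return AlignmentResult(
        offset_s=float(lags[best]),
        method="correlation",
        uncertainty_s=step,
        score=float(scores[best]),
        lags_s=tuple(lags),
    )
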