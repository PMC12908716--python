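"""GPS trajectory cleaning and movement summaries.

Raw pedestrian GNSS tracks contain fixes that jump several meters between
neighbouring samples and back — biologically impossible at walking speed —
alongside fixes degraded to an uncorrected single solution or recorded with
too few satellites. Cleaning proceeds in two tiers:

* strict — flag a fix if its quality code equals 5 (uncorrected single
  solution), it has fewer than 5 satellites, or its implied walking speed
  exceeds 6 km/h;
* relaxed — if a contiguous flagged run would leave more than 30 s of
  consecutive missing data, that run is re-evaluated with fewer than 4
  satellites and speeds above 7 km/h (quality rule unchanged), and only
  fixes the relaxed rule still condemns stay removed.

Speeds are computed greedily against the last *retained* fix, so an isolated
teleport condemns only itself, not the legitimate fix that follows it.
Camera (action-cam) tracks carry a per-fix precision estimate instead of
quality/satellite metadata; there the attribute rule is precision above the
session mean plus three standard deviations.

Removed fixes are linearly interpolated in latitude/longitude against time
between their retained neighbours; leading/trailing removals are dropped
(no extrapolation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, OrderingError
from .records import SINGLE_SOLUTION_QUALITY, GeoTrack

log = logging.getLogger("fieldgaze.gps")

EARTH_RADIUS_M = 6_371_000.0

STRICT = {"max_speed_kmh": 6.0, "min_satellites": 5, "bad_quality": SINGLE_SOLUTION_QUALITY}
RELAXED = {"max_speed_kmh": 7.0, "min_satellites": 4, "bad_quality": SINGLE_SOLUTION_QUALITY}
MAX_GAP_SECONDS = 30.0


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in meters (mean Earth radius 6 371 000 m)."""
    p1, l1, p2, l2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    s = np.sin((p2 - p1) / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))


def fix_speed(a, b) -> float:
    """Implied speed between two fixes in km/h (great-circle / Δt)."""
    dt = float(b["t"]) - float(a["t"])
    if dt <= 0:
        raise OrderingError(f"non-positive time difference {dt}")
    d = float(haversine_m(a["lat"], a["lon"], b["lat"], b["lon"]))
    return d / dt * 3.6


@dataclass
class CleaningReport:
    """Per-fix flagging decisions plus the tier bookkeeping of one cleaning."""

    reasons: list = field(default_factory=list)  # one (possibly empty) set per fix
    removed: list = field(default_factory=list)  # indices removed
    runs: list = field(default_factory=list)  # dicts: start, stop, tier, span_s, rescued
    interpolated: list = field(default_factory=list)
    dropped_edges: list = field(default_factory=list)
    speeds_kmh: list = field(default_factory=list)  # raw consecutive-pair speeds
    source: str = "rtk"

    @property
    def n_flagged(self) -> int:
        return sum(1 for r in self.reasons if r)

    def reason_counts(self) -> dict:
        out: dict = {}
        for i in self.removed:
            for reason in self.reasons[i]:
                out[reason] = out.get(reason, 0) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "n_fixes": len(self.reasons),
            "n_flagged": self.n_flagged,
            "n_removed": len(self.removed),
            "reason_counts": self.reason_counts(),
            "runs": [
                {k: (list(v) if isinstance(v, (list, tuple)) else v) for k, v in run.items()}
                for run in self.runs
            ],
            "n_interpolated": len(self.interpolated),
            "n_dropped_edges": len(self.dropped_edges),
        }


def _attr_reasons_rtk(row, tier) -> set:
    reasons = set()
    if not np.isnan(row["quality"]) and int(row["quality"]) == tier["bad_quality"]:
        reasons.add("quality")
    if not np.isnan(row["n_satellites"]) and row["n_satellites"] < tier["min_satellites"]:
        reasons.add("satellites")
    return reasons


def _greedy_flag(df: pd.DataFrame, indices, attr_fn, max_speed_kmh, last_retained):
    """Greedy forward pass: speed is always computed against the last
    retained fix, so a single displaced fix cannot condemn its successor."""
    reasons = {}
    for i in indices:
        row = df.iloc[i]
        r = set(attr_fn(row))
        if last_retained is not None:
            speed = fix_speed(df.iloc[last_retained], row)
            if speed > max_speed_kmh:
                r.add("speed")
        if r:
            reasons[i] = r
        else:
            last_retained = i
    return reasons, last_retained


def _flagged_runs(flagged: set, n: int):
    runs = []
    i = 0
    while i < n:
        if i in flagged:
            j = i
            while j + 1 < n and (j + 1) in flagged:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def flag_outliers_rtk(track: GeoTrack) -> CleaningReport:
    """Two-tier strict/relaxed outlier flagging for RTK GNSS tracks.

    Strict criteria are applied in a greedy forward pass; any contiguous
    flagged run whose missing-data span (time between the retained
    neighbours) exceeds 30 s is re-evaluated once under the relaxed
    criteria, and fixes the relaxed rule clears are reinstated.
    """
    df = track.data
    n = len(df)
    if n < 2:
        raise DegenerateInputError("track shorter than 2 fixes")
    t = track.t

    strict_fn = lambda row: _attr_reasons_rtk(row, STRICT)  # noqa: E731
    relaxed_fn = lambda row: _attr_reasons_rtk(row, RELAXED)  # noqa: E731

    reasons_map, _ = _greedy_flag(df, range(n), strict_fn, STRICT["max_speed_kmh"], None)
    flagged = set(reasons_map)

    report = CleaningReport(source="rtk")
    for start, stop in _flagged_runs(flagged, n):
        prev_ret = start - 1 if start > 0 else None
        next_ret = stop + 1 if stop + 1 < n else None
        lo = t[prev_ret] if prev_ret is not None else t[start]
        hi = t[next_ret] if next_ret is not None else t[stop]
        span = float(hi - lo)
        tier = "strict"
        rescued = []
        if span > MAX_GAP_SECONDS:
            tier = "relaxed"
            rel_reasons, _ = _greedy_flag(
                df, range(start, stop + 1), relaxed_fn,
                RELAXED["max_speed_kmh"], prev_ret,
            )
            for i in range(start, stop + 1):
                if i in rel_reasons:
                    reasons_map[i] = rel_reasons[i]
                else:
                    rescued.append(i)
                    del reasons_map[i]
            log.info(
                "gap %.1f s (fixes %d-%d) > %.0f s: relaxed tier rescued %d/%d fixes",
                span, start, stop, MAX_GAP_SECONDS, len(rescued), stop - start + 1,
            )
        report.runs.append(
            {"start": int(start), "stop": int(stop), "tier": tier,
             "span_s": span, "rescued": rescued}
        )

    report.reasons = [reasons_map.get(i, set()) for i in range(n)]
    report.removed = sorted(reasons_map)
    report.speeds_kmh = [
        fix_speed(df.iloc[i], df.iloc[i + 1]) for i in range(n - 1)
    ]
    return report


def flag_outliers_camera(track: GeoTrack) -> CleaningReport:
    """Outlier flagging for camera GPS: speed > 6 km/h (greedy) or precision
    above the session's mean + 3·sd of the raw precision values."""
    df = track.data
    n = len(df)
    if n < 2:
        raise DegenerateInputError("track shorter than 2 fixes")
    prec = df["precision"].to_numpy(dtype=float)
    if np.isnan(prec).any():
        raise FormatError("camera track requires a precision value on every fix")
    threshold = prec.mean() + 3.0 * prec.std(ddof=1) if n > 1 else prec.mean()

    def attr_fn(row):
        return {"precision"} if row["precision"] > threshold else set()

    reasons_map, _ = _greedy_flag(df, range(n), attr_fn, STRICT["max_speed_kmh"], None)
    report = CleaningReport(source="camera")
    report.reasons = [reasons_map.get(i, set()) for i in range(n)]
    report.removed = sorted(reasons_map)
    report.speeds_kmh = [fix_speed(df.iloc[i], df.iloc[i + 1]) for i in range(n - 1)]
    for start, stop in _flagged_runs(set(reasons_map), n):
        prev_ret = start - 1 if start > 0 else None
        next_ret = stop + 1 if stop + 1 < n else None
        lo = track.t[prev_ret] if prev_ret is not None else track.t[start]
        hi = track.t[next_ret] if next_ret is not None else track.t[stop]
        report.runs.append(
            {"start": int(start), "stop": int(stop), "tier": "camera",
             "span_s": float(hi - lo), "rescued": []}
        )
    return report


def clean_track(track: GeoTrack, report: CleaningReport) -> GeoTrack:
    """Remove flagged fixes and linearly interpolate the gaps.

    Interior removed fixes are replaced at their original timestamps by
    linear interpolation of latitude and longitude against time between the
    nearest retained neighbours; leading/trailing removed fixes are dropped.
    ``report.interpolated`` / ``report.dropped_edges`` are filled in place.
    """
    n = len(track)
    if len(report.reasons) != n:
        raise DegenerateInputError("report does not match track length")
    removed = set(report.removed)
    kept = [i for i in range(n) if i not in removed]
    if not kept:
        raise DegenerateInputError("all fixes removed")
    first, last = kept[0], kept[-1]
    interior = [i for i in sorted(removed) if first < i < last]
    edges = [i for i in sorted(removed) if i < first or i > last]

    t = track.t
    kt = t[kept]
    out = track.data.copy()
    if "interpolated" not in out.columns:
        out["interpolated"] = False
    if interior:
        out.loc[interior, "lat"] = np.interp(t[interior], kt, track.lat[kept])
        out.loc[interior, "lon"] = np.interp(t[interior], kt, track.lon[kept])
        out.loc[interior, ["quality", "n_satellites", "precision"]] = np.nan
        out.loc[interior, "interpolated"] = True
    keep_rows = sorted(set(kept) | set(interior))
    out = out.iloc[keep_rows]
    report.interpolated = interior
    report.dropped_edges = edges
    return GeoTrack(out, source=track.source)


def track_summary(track: GeoTrack) -> dict:
    """Mean ± sample sd of inter-fix speeds, path length and duration.

    Calibration phases must be excluded (cropped) by the caller before the
    summary; the summary itself is purely kinematic.
    """
    n = len(track)
    if n < 2:
        raise DegenerateInputError("track shorter than 2 fixes")
    t, lat, lon = track.t, track.lat, track.lon
    d = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    dt = np.diff(t)
    speeds = d / dt * 3.6
    return {
        "n_fixes": n,
        "mean_speed_kmh": float(speeds.mean()),
        "sd_speed_kmh": float(speeds.std(ddof=1)) if n > 2 else float("nan"),
        "path_length_m": float(d.sum()),
        "duration_s": float(t[-1] - t[0]),
    }
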