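"""Scoring of pointing-to-north and pointing-to-building trials.

The participant stands at a known location (marked on a map, not taken from
the GPS stream) and points a compass-equipped device at true north and at a
set of known buildings. Each trial is scored against the initial
great-circle bearing from the participant's location to the target,

    θ = atan2(sin Δλ · cos φ2,  cos φ1 · sin φ2 − sin φ1 · cos φ2 · cos Δλ),

with latitudes/longitudes in radians and θ converted to cardinal degrees.
Compass read-outs are magnetic; adding the (east-positive) local magnetic
declination references them to true north before differencing. Errors are
signed shortest-arc differences; groups are summarized as mean ± sample sd
of absolute error, and the error–confidence relation is assessed with an
exact Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import circ_diff, circular_mean, circular_sd, wrap_cardinal
from .errors import CoverageError, ParameterError, UndefinedBearingError
from .exact_stats import TestResult, spearman_correlation
from .records import PointingTrial


def true_bearing(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Initial great-circle bearing from point 1 to point 2, cardinal degrees."""
    if lat1 == lat2 and lon1 == lon2:
        raise UndefinedBearingError("bearing undefined between coincident points")
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dl = l2 - l1
    theta = np.arctan2(
        np.sin(dl) * np.cos(p2),
        np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl),
    )
    return float(wrap_cardinal(np.degrees(theta)))


def apply_declination(compass_reading_deg: float, declination_deg: float) -> float:
    """True-north heading from a magnetic reading (east-positive declination)."""
    if not (0.0 <= compass_reading_deg < 360.0):
        raise ParameterError("compass reading outside [0, 360)")
    return float(wrap_cardinal(compass_reading_deg + declination_deg))


@dataclass(frozen=True)
class PointingScore:
    """Scored pointing trial: true vs pointed direction and their error."""

    trial_id: str
    task: str
    target_id: str | None
    true_bearing_deg: float  # [0, 360)
    pointed_true_deg: float  # [0, 360)
    signed_error_deg: float  # (−180, 180]
    confidence: int | None = None

    @property
    def abs_error_deg(self) -> float:
        return abs(self.signed_error_deg)


def pointing_error(trial: PointingTrial) -> PointingScore:
    """Score one trial: signed error = pointed_true − true_bearing, wrapped.

    North trials are scored against a true bearing of 0° (true north).
    """
    if trial.task == "north":
        bearing = 0.0
    else:
        bearing = true_bearing(trial.lat1, trial.lon1, trial.lat2, trial.lon2)
    pointed = apply_declination(trial.compass_reading_deg, trial.declination_deg)
    err = float(circ_diff(pointed, bearing))
    return PointingScore(
        trial_id=trial.trial_id,
        task=trial.task,
        target_id=trial.target_id,
        true_bearing_deg=bearing,
        pointed_true_deg=pointed,
        signed_error_deg=err,
        confidence=trial.confidence,
    )


def score_trials(trials) -> list[PointingScore]:
    return [pointing_error(t) for t in trials]


def aggregate_scores(scores, group_by: str = "task") -> pd.DataFrame:
    """Mean ± sample sd of absolute error per group (task or target).

    Also reports the circular mean and circular sd of the signed errors per
    group. The sd is absent (NaN) for single-trial groups.
    """
    if group_by not in ("task", "target"):
        raise ParameterError("group_by must be 'task' or 'target'")
    if not scores:
        raise CoverageError("no scores to aggregate")
    df = pd.DataFrame(
        [
            {
                "task": s.task,
                "target": s.target_id if s.target_id is not None else s.task,
                "abs_error_deg": s.abs_error_deg,
                "signed_error_deg": s.signed_error_deg,
                "confidence": s.confidence,
            }
            for s in scores
        ]
    )
    rows = []
    for key, grp in df.groupby(group_by, sort=True):
        n = len(grp)
        rows.append(
            {
                group_by: key,
                "n": n,
                "mean_abs_error_deg": float(grp["abs_error_deg"].mean()),
                "sd_abs_error_deg": (
                    float(grp["abs_error_deg"].std(ddof=1)) if n > 1 else float("nan")
                ),
                "circular_mean_signed_deg": circular_mean(grp["signed_error_deg"]),
                "circular_sd_signed_deg": (
                    circular_sd(grp["signed_error_deg"]) if n > 1 else float("nan")
                ),
                "mean_confidence": (
                    float(grp["confidence"].mean())
                    if grp["confidence"].notna().any()
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def confidence_correlation(per_target: pd.DataFrame) -> TestResult:
    """Spearman correlation between per-target mean |error| and confidence.

    Accepts the output of ``aggregate_scores(..., group_by='target')`` (or
    any frame with mean_abs_error_deg and mean_confidence columns); exact
    permutation p for up to 9 targets.
    """
    df = per_target.dropna(subset=["mean_abs_error_deg", "mean_confidence"])
    return spearman_correlation(
        df["mean_abs_error_deg"].to_numpy(), df["mean_confidence"].to_numpy()
    )
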