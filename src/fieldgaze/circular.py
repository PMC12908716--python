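"""Circular (angular) helpers shared across the pipeline.

Conventions
-----------
* *Cardinal degrees*: compass convention, 0° = north, clockwise positive,
  range [0, 360).
* *Signed degrees*: the wrapped difference convention, range (−180, 180].
* A device yaw channel reports signed degrees; compasses report cardinal.
"""

from __future__ import annotations

import numpy as np

from .errors import EmptyInputError


def wrap_signed(angle_deg):
    """Wrap angle(s) in degrees into (−180, 180].

    The branch point maps −180 to +180, so the output interval is half-open
    on the left, matching the yaw convention of the head tracker.
    """
    return 180.0 - np.mod(180.0 - np.asarray(angle_deg, dtype=float), 360.0)


def wrap_cardinal(angle_deg):
    """Wrap angle(s) in degrees into [0, 360)."""
    w = np.mod(np.asarray(angle_deg, dtype=float), 360.0)
    # np.mod(-eps, 360) rounds to 360.0; keep the interval half-open
    return np.where(w == 360.0, 0.0, w)


def circ_diff(a_deg, b_deg):
    """Signed shortest-arc difference a − b, in (−180, 180]."""
    return wrap_signed(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))


def circular_median(angles_deg) -> float:
    """Median direction of a sample of angles (degrees, any convention).

    Returns the sample angle minimizing the summed absolute circular
    (shorter-arc) distance to all other samples, found by exhaustive search.
    Ties (e.g. an even sample with two central candidates) are resolved by
    the circular mean of the tied minimizers, which reduces to the familiar
    midpoint convention away from the wrap.

    The result is reported in cardinal degrees [0, 360).
    """
    a = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise EmptyInputError("circular_median of an empty sample")
    costs = np.abs(circ_diff(a[None, :], a[:, None])).sum(axis=1)
    best = np.flatnonzero(np.isclose(costs, costs.min(), rtol=0, atol=1e-9))
    if best.size == 1:
        return float(wrap_cardinal(a[best[0]]))
    return float(wrap_cardinal(circular_mean(a[best])))


def circular_mean(angles_deg) -> float:
    """Mean direction (cardinal degrees) via the resultant vector."""
    a = np.radians(np.atleast_1d(np.asarray(angles_deg, dtype=float)))
    if a.size == 0:
        raise EmptyInputError("circular_mean of an empty sample")
    return float(np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean())) % 360.0)


def circular_sd(angles_deg) -> float:
    """Circular standard deviation in degrees, sqrt(−2 ln R̄).

    For small dispersion this converges to the linear standard deviation,
    which makes it the natural check against a wrapped-Gaussian generator.
    """
    a = np.radians(np.atleast_1d(np.asarray(angles_deg, dtype=float)))
    if a.size == 0:
        raise EmptyInputError("circular_sd of an empty sample")
    r = np.hypot(np.sin(a).mean(), np.cos(a).mean())
    r = min(max(r, 1e-300), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def unwrap_deg(angles_deg) -> np.ndarray:
    """Unwrap a degree series into a continuous curve (no 360° jumps)."""
    return np.degrees(np.unwrap(np.radians(np.asarray(angles_deg, dtype=float))))
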