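"""Angle conventions and circular/axial helpers.

Convention used throughout the package
--------------------------------------
Images are indexed ``[row, col]`` with the origin at the top-left pixel
center.  The x axis points rightward along columns and the y axis points
*downward* along rows (image display convention).  Angles are measured from
the +x axis, **counterclockwise-positive as seen on screen** — i.e. a
positive angle tilts a direction vector from +x toward *decreasing* row
index.  Numerically this is ``atan2(-d_row, d_col)``.

Orientations of line-like texture are *axial* quantities: they live on
[0, 180) degrees and statistics on them use the angle-doubling transform
(an axial angle theta is mapped to 2*theta on the full circle, summarized
there, and halved back).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "vector_angle_deg",
    "wrap_axial_deg",
    "signed_axial_diff_deg",
    "axial_resultant",
    "axial_circmean_deg",
    "axial_circstd_deg",
    "ring_tangent_deg",
]


def vector_angle_deg(d_col, d_row):
    """Angle of a displacement (d_col, d_row) in screen-CCW degrees."""
    return np.degrees(np.arctan2(-np.asarray(d_row, float), np.asarray(d_col, float)))


def wrap_axial_deg(angle_deg):
    """Reduce an angle to the axial range [0, 180)."""
    return np.mod(angle_deg, 180.0)


def signed_axial_diff_deg(a_deg, b_deg):
    """Signed axial difference a - b mapped to (-90, 90].

    Positive means *a* is rotated counterclockwise (on screen) from *b*.
    """
    d = np.mod(np.asarray(a_deg, float) - np.asarray(b_deg, float) + 90.0, 180.0) - 90.0
    # fold the open end: -90 is the same axis as +90, report +90
    d = np.where(np.isclose(d, -90.0), 90.0, d)
    return d if d.ndim else float(d)


def axial_resultant(angles_deg, weights=None):
    """Weighted circular resultant on doubled angles.

    Returns (mean_axial_deg in [0, 180), resultant_length in [0, 1]).
    """
    a = np.radians(2.0 * np.asarray(angles_deg, float))
    if weights is None:
        weights = np.ones_like(a)
    w = np.asarray(weights, float)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("total weight must be positive")
    z = np.sum(w * np.exp(1j * a)) / tot
    mean = wrap_axial_deg(np.degrees(np.angle(z)) / 2.0)
    return float(mean), float(np.abs(z))


def axial_circmean_deg(angles_deg, weights=None):
    return axial_resultant(angles_deg, weights)[0]


def axial_circstd_deg(angles_deg, weights=None):
    """Circular standard deviation on doubled angles, halved back (degrees)."""
    _, r = axial_resultant(angles_deg, weights)
    if r <= 0:
        return np.inf
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))) / 2.0)


def ring_tangent_deg(x, y, center_xy):
    """Axial angle of the circle tangent at point(s) (x, y) around a center.

    x, y and the center are in the same units, (col, row)-ordered. The
    tangent is the circumferential direction; returned in [0, 180).
    """
    dx = np.asarray(x, float) - center_xy[0]
    dy = np.asarray(y, float) - center_xy[1]
    if np.any((dx == 0) & (dy == 0)):
        raise ValueError("tangent undefined at the ring center")
    # radial direction in the screen-CCW (y-up) frame is (dx, -dy); the CCW
    # tangent is that rotated by +90 deg: (dy, dx) in y-up components.
    return wrap_axial_deg(np.degrees(np.arctan2(dx, dy)))
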