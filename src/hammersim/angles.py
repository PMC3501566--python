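"""Planar angle conventions used throughout the package.

Angles are in degrees, counterclockwise-positive when the workspace is
viewed from above.  0 deg points away from the subject along +y; the tool
orientation is the direction of the rod from the handle to the head.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_deg",
    "ang_diff_deg",
    "bearing_to_vec",
    "vec_to_bearing",
    "rot2d",
]


def wrap_deg(a):
    """Wrap angle(s) to the half-open interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return w if w.ndim else float(w)


def ang_diff_deg(a, b):
    """Signed wrapped difference a - b in (-180, 180]."""
    return wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def bearing_to_vec(bearing_deg):
    """Unit vector(s) for a bearing: 0 deg -> +y, 90 deg -> -x (CCW positive)."""
    b = np.deg2rad(np.asarray(bearing_deg, dtype=float))
    return np.stack([-np.sin(b), np.cos(b)], axis=-1)


def vec_to_bearing(v):
    """Bearing in degrees of planar vector(s), inverse of :func:`bearing_to_vec`."""
    v = np.asarray(v, dtype=float)
    b = np.rad2deg(np.arctan2(-v[..., 0], v[..., 1]))
    return wrap_deg(b)


def rot2d(delta_deg):
    """2x2 rotation matrix rotating vectors CCW by ``delta_deg``."""
    d = np.deg2rad(float(delta_deg))
    c, s = np.cos(d), np.sin(d)
    return np.array([[c, -s], [s, c]])
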