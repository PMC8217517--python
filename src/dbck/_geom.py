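"""Small planar-geometry helpers shared across modules.

All coordinates are 2-D, in nanometres, following the package-wide
convention: head long axis along +x, neck at the origin, +y = the
sperm's right side.
"""
from __future__ import annotations

import numpy as np


def rotation_matrix(angle_rad: float) -> np.ndarray:
    """Counterclockwise rotation matrix for `angle_rad` radians."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s], [s, c]])


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("zero-length vector has no direction")
    return v / n


def cross2(u: np.ndarray, v: np.ndarray) -> float:
    """Scalar z-component of the 2-D cross product u x v."""
    return float(u[0] * v[1] - u[1] * v[0])


def signed_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Signed angle (radians, in (-pi, pi]) rotating u onto v, CCW positive."""
    u, v = unit(u), unit(v)
    ang = float(np.arctan2(cross2(u, v), float(np.dot(u, v))))
    if ang <= -np.pi:
        ang += 2 * np.pi
    return ang


def perp_distance_to_line(point: np.ndarray, line_point: np.ndarray,
                          line_dir: np.ndarray) -> float:
    """Unsigned perpendicular distance from `point` to the infinite line."""
    d = unit(line_dir)
    r = np.asarray(point, dtype=float) - np.asarray(line_point, dtype=float)
    return abs(cross2(d, r))


def signed_lateral_offset(point: np.ndarray, line_point: np.ndarray,
                          rostral_dir: np.ndarray) -> float:
    """Signed perpendicular offset of `point` from a midline.

    Positive on the sperm's right. With the rostral direction r̂, the
    rightward normal is r̂ rotated by -90°, so the offset is
    -cross(r̂, point - line_point).
    """
    d = unit(rostral_dir)
    r = np.asarray(point, dtype=float) - np.asarray(line_point, dtype=float)
    return -cross2(d, r)
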