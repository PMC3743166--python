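"""Small geometric primitives shared across modules.

All angles are degrees, all lengths Angstrom, all frames right-handed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rotation_about_axis",
    "rotation_z",
    "dihedral",
    "fit_plane",
    "fit_line",
    "angle_to_plane",
    "PlaneFitError",
]


class PlaneFitError(ValueError):
    """Raised when points are too degenerate (collinear) to define a plane."""


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalise the zero vector")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 proper rotation matrix about ``axis`` by ``angle_deg`` (Rodrigues)."""
    k = unit(axis)
    t = np.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def rotation_z(angle_deg: float) -> np.ndarray:
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through ``points``: returns (centroid, unit normal).

    Raises :class:`PlaneFitError` for fewer than 3 points or collinear sets.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise PlaneFitError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise PlaneFitError("points are collinear; plane undefined")
    return centroid, vt[2]


def fit_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares line through ``points``: returns (centroid, unit direction)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("line fit needs at least 2 points")
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[0]


def angle_to_plane(vector: np.ndarray, normal: np.ndarray) -> float:
    """Angle in degrees between ``vector`` and the plane with unit ``normal``.

    0 for an in-plane vector, 90 for a vector along the normal.
    """
    v = unit(vector)
    n = unit(normal)
    s = np.clip(abs(np.dot(v, n)), 0.0, 1.0)
    return float(np.degrees(np.arcsin(s)))
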