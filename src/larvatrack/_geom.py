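"""Small planar-geometry helpers shared by the tracking and fixture modules.

Coordinate convention everywhere: (x right, y down), 0-based pixel indices,
component centroids at pixel centres.  Angles are measured from the +x axis,
counter-clockwise in (x, y) as drawn (which is clockwise on screen with y
down); "larva's left" corresponds to positive signed angles under this
convention.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(a):
    """Wrap angle(s) into [0, 2*pi)."""
    return np.mod(a, TWO_PI)


def wrap_signed(a):
    """Wrap angle(s) into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a), TWO_PI)


def unit(angle: float) -> np.ndarray:
    return np.array([np.cos(angle), np.sin(angle)])


def signed_angle(v_from: np.ndarray, v_to: np.ndarray) -> float:
    """Signed angle (rad, in (-pi, pi]) rotating v_from onto v_to."""
    cross = v_from[0] * v_to[1] - v_from[1] * v_to[0]
    dot = v_from[0] * v_to[0] + v_from[1] * v_to[1]
    return float(np.arctan2(cross, dot))


def rotate(points: np.ndarray, angle: float, origin=(0.0, 0.0)) -> np.ndarray:
    """Rotate (N, 2) points by *angle* around *origin*."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    pts = np.asarray(points, dtype=float) - origin
    return pts @ rot.T + origin


def polyline_length(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def arc_lengths(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length along a polyline, starting at 0."""
    pts = np.asarray(points, dtype=float)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to *n* points equally spaced in arc length."""
    pts = np.asarray(points, dtype=float)
    s = arc_lengths(pts)
    if s[-1] == 0:
        return np.repeat(pts[:1], n, axis=0)
    target = np.linspace(0.0, s[-1], n)
    x = np.interp(target, s, pts[:, 0])
    y = np.interp(target, s, pts[:, 1])
    return np.column_stack([x, y])
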