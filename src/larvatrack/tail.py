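"""Tail extraction: full body, tail tip, midline, bend angle.

The tail tip is found by the contour-candidate procedure: the body contour
is traced, rotated so the head axis is vertical with the head on top, and
four extremal contour points caudal to two near-head reference points are
scored; candidates whose contour-arc distances to the two reference points
are too asymmetric are discarded, and the tip is the candidate where the
contour turns most sharply (smallest scalar product of the travel-direction
tangents before and after the point).

The midline is the line equidistant from the left and right contour arcs,
smoothed with a spline and resampled to ten points from the head centre to
the tail tip.  A tail is accepted only if its length falls inside the
configured physical bounds; otherwise the previous frame's tail is carried.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import interpolate, ndimage, signal
from skimage import measure

from ._geom import arc_lengths, resample_polyline, rotate, signed_angle, unit
from .calibration import CalibrationConfig
from .tracking import LarvaState

__all__ = [
    "TailMidline", "BodyMissingError", "TipNotFoundError",
    "extract_full_body", "body_contour", "head_center_from_core",
    "find_tail_tip", "compute_midline", "compute_bend_angle",
    "clean_trace", "track_tail",
]


class BodyMissingError(RuntimeError):
    pass


class TipNotFoundError(RuntimeError):
    pass


@dataclasses.dataclass
class TailMidline:
    larva_id: int
    frame: int
    points: np.ndarray          # (10, 2) head centre first, tail tip last
    tail_length_mm: float
    valid: bool

    @property
    def tip(self) -> np.ndarray:
        return self.points[-1]


# ----------------------------------------------------------------------
def extract_full_body(binary: np.ndarray, core_position: np.ndarray) -> np.ndarray:
    """4-connected component of the pre-erosion binary containing the core.

    If the core centroid lands on background (possible after rounding), the
    3x3 neighbourhood is searched; failing that the body is missing.
    Returns a boolean mask of the component.
    """
    labels, n = ndimage.label(binary, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
    x, y = int(round(core_position[0])), int(round(core_position[1]))
    h, w = binary.shape
    lab = 0
    for dy, dx in [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1),
                   (-1, -1), (-1, 1), (1, -1), (1, 1)]:
        yy, xx = y + dy, x + dx
        if 0 <= yy < h and 0 <= xx < w and labels[yy, xx]:
            lab = labels[yy, xx]
            break
    if lab == 0:
        raise BodyMissingError(f"no body at core position ({x}, {y})")
    return labels == lab


def body_contour(mask: np.ndarray) -> np.ndarray:
    """Outer contour of a body mask as ordered (x, y) points."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise BodyMissingError("empty body mask")
    c = max(contours, key=len)
    if np.allclose(c[0], c[-1]):
        c = c[:-1]
    return c[:, ::-1].copy()   # (row, col) -> (x, y)


def head_center_from_core(position: np.ndarray, heading: float,
                          core_area: float) -> np.ndarray:
    """Head centre at the head/trunk boundary: the eroded-core centroid
    shifted tailward along the heading axis by one head radius."""
    return position - np.sqrt(core_area / np.pi) * unit(heading)


# ----------------------------------------------------------------------
def _cyclic_arc_distance(s: np.ndarray, i: int, j: int) -> float:
    """Shorter arc length between contour indices i, j on a closed contour."""
    total = s[-1]
    d = abs(s[i] - s[j])
    return min(d, total - d)


def find_tail_tip(mask: np.ndarray, state: LarvaState, core_area: float,
                  cfg: CalibrationConfig, tangent_step: int = 4,
                  ) -> np.ndarray:
    """Locate the tail tip on the body contour (original coordinates)."""
    contour = body_contour(mask)
    hc = head_center_from_core(state.position, state.heading, core_area)
    # rotate so the tailward direction maps to +y (head axis vertical,
    # head at the top)
    delta = np.pi / 2 - (state.heading + np.pi)
    rot = rotate(contour, delta, origin=hc)
    hc_rot = hc

    d_head = np.hypot(rot[:, 0] - hc_rot[0], rot[:, 1] - hc_rot[1])
    i_a1 = int(np.argmin(d_head))
    # A2: contour point nearest the mirror of A1 across the head axis (x = hc_x)
    a1 = rot[i_a1]
    mirror = np.array([2 * hc_rot[0] - a1[0], a1[1]])
    i_a2 = int(np.argmin(np.hypot(rot[:, 0] - mirror[0], rot[:, 1] - mirror[1])))
    a2 = rot[i_a2]

    # closed-contour arc length including the closing segment
    s_open = arc_lengths(rot)
    closing = np.hypot(*(rot[0] - rot[-1]))
    s = np.append(s_open, s_open[-1] + closing)

    y_ref = max(a1[1], a2[1])
    caudal = np.nonzero(rot[:, 1] > y_ref)[0]
    if caudal.size == 0:
        raise TipNotFoundError("no contour points caudal to the reference points")

    cand_idx = {
        "min_x": caudal[np.argmin(rot[caudal, 0])],
        "max_x": caudal[np.argmax(rot[caudal, 0])],
        "min_y": caudal[np.argmin(rot[caudal, 1])],
        "max_y": caudal[np.argmax(rot[caudal, 1])],
    }
    survivors = []
    for name, i in cand_idx.items():
        d1 = _cyclic_arc_distance(s, i, i_a1)
        d2 = _cyclic_arc_distance(s, i, i_a2)
        if d1 + d2 == 0:
            continue
        ratio = abs(d1 - d2) / (d1 + d2)
        if ratio > cfg.candidate_ratio_hard:
            continue
        if name == "max_y" and ratio > cfg.candidate_ratio_soft:
            continue
        survivors.append(int(i))
    if not survivors:
        raise TipNotFoundError("all tail-tip candidates excluded")

    n = len(rot)
    k = max(1, min(tangent_step, n // 4))
    best, best_score = survivors[0], np.inf
    for i in survivors:
        v1 = rot[(i + k) % n] - rot[i]
        v2 = rot[i] - rot[(i - k) % n]
        n1, n2 = np.hypot(*v1), np.hypot(*v2)
        if n1 == 0 or n2 == 0:
            continue
        score = float(np.dot(v1, v2) / (n1 * n2))
        if score < best_score:
            best, best_score = i, score
    return contour[best].copy()


# ----------------------------------------------------------------------
def compute_midline(mask: np.ndarray, head_center: np.ndarray,
                    tip: np.ndarray, cfg: CalibrationConfig,
                    larva_id: int = 0, frame: int = 0,
                    n_points: int = 10) -> TailMidline:
    """Midline equidistant from the left and right contour arcs.

    The contour is split at the tip and at the point nearest the head
    centre on either side; both arcs are resampled to equal counts and
    averaged, a smoothing spline is fitted, and the result is resampled to
    ``n_points`` equally arc-spaced points from the head centre to the tip.
    """
    contour = body_contour(mask)
    n = len(contour)
    i_tip = int(np.argmin(np.hypot(contour[:, 0] - tip[0],
                                   contour[:, 1] - tip[1])))
    contour = np.roll(contour, -i_tip, axis=0)   # tip at index 0
    d_head = np.hypot(contour[:, 0] - head_center[0],
                      contour[:, 1] - head_center[1])
    i_a1 = int(np.argmin(d_head))
    # the matching point on the opposite flank: nearest the head centre but
    # far from A1 along the contour (the two flanks are close in space yet
    # far apart in contour index)
    idx = np.arange(n)
    cyc = np.minimum(np.abs(idx - i_a1), n - np.abs(idx - i_a1))
    far = cyc > 0.15 * n
    if not far.any():
        raise TipNotFoundError("contour too short to split into two flanks")
    i_a2 = int(idx[far][np.argmin(d_head[far])])
    lo, hi = sorted((i_a1, i_a2))
    arc_a = contour[:lo + 1]                     # tip -> near-head, one side
    arc_b = np.vstack([contour[hi:], contour[:1]])[::-1]   # tip -> near-head
    if len(arc_a) < 3 or len(arc_b) < 3:
        raise TipNotFoundError("contour arcs too short for a midline")
    m = max(len(arc_a), len(arc_b), 20)
    mid = (resample_polyline(arc_a, m) + resample_polyline(arc_b, m)) / 2.0
    mid = np.vstack([mid[::-1], [tip]])          # head end first
    mid[0] = head_center

    # smoothing spline on the centre positions
    s = arc_lengths(mid)
    if s[-1] == 0:
        raise TipNotFoundError("degenerate midline")
    u = s / s[-1]
    smooth = len(mid) * cfg.spline_smooth_px ** 2
    try:
        (tck, _) = interpolate.splprep([mid[:, 0], mid[:, 1]], u=u, s=smooth, k=3)
        dense = np.column_stack(interpolate.splev(np.linspace(0, 1, 200), tck))
    except Exception:
        dense = mid
    pts = resample_polyline(dense, n_points)
    length_mm = cfg.to_mm(arc_lengths(dense)[-1])
    valid = cfg.tail_length_min_mm < length_mm < cfg.tail_length_max_mm
    return TailMidline(larva_id, frame, pts, length_mm, valid)


def compute_bend_angle(midline: TailMidline, state: LarvaState) -> float:
    """Signed tail-bending angle (deg) between the tailward body axis and
    the head-centre -> tail-tip line.  Positive: tip on the larva's left."""
    tailward = -unit(state.heading)
    v = midline.tip - midline.points[0]
    if np.hypot(*v) == 0:
        raise ValueError("zero-length head-to-tip vector")
    return float(np.rad2deg(signed_angle(tailward, v)))


def clean_trace(angles: np.ndarray, valid: np.ndarray,
                cfg: CalibrationConfig) -> np.ndarray:
    """Carry previous valid values over invalid frames, then median-filter."""
    angles = np.asarray(angles, dtype=float).copy()
    valid = np.asarray(valid, dtype=bool)
    if valid.any():
        first = np.flatnonzero(valid)[0]
        angles[:first] = angles[first]
        for i in range(first + 1, len(angles)):
            if not valid[i]:
                angles[i] = angles[i - 1]
    else:
        angles[:] = 0.0
    win = cfg.median_filter_frames
    if win % 2 == 0:
        win += 1
    if len(angles) >= win:
        angles = signal.medfilt(angles, win)
    return angles


# ----------------------------------------------------------------------
def track_tail(binary: np.ndarray, state: LarvaState, core_area: float,
               cfg: CalibrationConfig, prev: TailMidline | None,
               ) -> TailMidline:
    """One larva, one frame: full body -> tip -> midline, with carry-over.

    On any failure (missing body, no surviving tip candidate, tail length
    out of bounds) the previous frame's midline is returned flagged
    invalid, matching the carry-forward policy of the upstream stages.
    """
    try:
        mask = extract_full_body(binary, state.position)
        tip = find_tail_tip(mask, state, core_area, cfg)
        hc = head_center_from_core(state.position, state.heading, core_area)
        mid = compute_midline(mask, hc, tip, cfg, state.larva_id, state.frame)
        if mid.valid:
            return mid
    except (BodyMissingError, TipNotFoundError):
        pass
    if prev is not None:
        return TailMidline(state.larva_id, state.frame, prev.points.copy(),
                           prev.tail_length_mm, False)
    return TailMidline(state.larva_id, state.frame,
                       np.tile(state.position, (10, 1)).astype(float), 0.0, False)
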