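"""Core tracking: wells, background, segmentation, heading, identities.

The stages mirror the classic blob pipeline for dark larvae on a bright
field: per-well background as the pixel-wise maximum over frames (moving
dark objects vanish under a max projection), background subtraction, fixed
binarization, double 3x3 erosion, area-filtered connected components as
larva "cores", heading from second-order moments, and frame-to-frame
identity assignment by constant-velocity prediction to the closest core.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import feature
from skimage.transform import hough_circle, hough_circle_peaks

from ._geom import wrap_angle, wrap_signed
from .calibration import CalibrationConfig

__all__ = [
    "WellROI", "CoreCandidate", "LarvaState", "SegmentationResult",
    "WellDetectionError", "detect_wells", "estimate_background",
    "segment_cores", "compute_heading", "assign_identities", "IdentityTracker",
]

EROSION_STRUCTURE = np.ones((3, 3), dtype=bool)


class WellDetectionError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class WellROI:
    center: tuple[float, float]   # (x, y)
    radius: float
    index: int

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        return (xx - self.center[0]) ** 2 + (yy - self.center[1]) ** 2 <= self.radius ** 2


@dataclasses.dataclass
class CoreCandidate:
    centroid: np.ndarray          # (x, y)
    area: int
    pixels: tuple[np.ndarray, np.ndarray]   # (ys, xs) of the eroded component


@dataclasses.dataclass
class LarvaState:
    larva_id: int
    frame: int
    position: np.ndarray          # (x, y) core centroid, px
    heading: float                # rad, [0, 2*pi)
    valid: bool
    collision_with: int | None = None


@dataclasses.dataclass
class SegmentationResult:
    binary: np.ndarray            # pre-erosion foreground mask
    eroded: np.ndarray
    candidates: list[CoreCandidate]


# ----------------------------------------------------------------------
def detect_wells(frames, expected: int, radius_range=None,
                 bright_wells: bool = True) -> list[WellROI]:
    """Find circular wells with a Hough transform on the first frame.

    Returns exactly ``expected`` wells sorted row-major by centre, or raises
    :class:`WellDetectionError` reporting how many confident circles were
    found.
    """
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] < 1:
        raise ValueError("need at least one frame")
    img = frames[0].astype(float)
    if not bright_wells:
        img = img.max() - img
    h, w = img.shape
    if radius_range is None:
        rmax = min(h, w) // 2
        radius_range = np.arange(max(rmax // 6, 8), rmax, 4)
    else:
        radius_range = np.asarray(radius_range)
    edges = feature.canny(img / max(img.max(), 1.0), sigma=2.0)
    accum = hough_circle(edges, radius_range)
    min_dist = int(radius_range.min())
    _, cx, cy, radii = hough_circle_peaks(
        accum, radius_range, min_xdistance=min_dist, min_ydistance=min_dist,
        threshold=0.5 * accum.max() if accum.size else 1.0,
        total_num_peaks=expected + 4)
    n_found = len(cx)
    if n_found < expected:
        raise WellDetectionError(
            f"found {n_found} wells, expected {expected}")
    if n_found > expected:
        # extra weak circles beyond the expected count are tolerated only if
        # clearly weaker; hough_circle_peaks orders by accumulator value
        cx, cy, radii = cx[:expected], cy[:expected], radii[:expected]
    rows = np.round(cy / np.mean(radii)).astype(int)
    order = np.lexsort((cx, rows))
    return [WellROI((float(cx[i]), float(cy[i])), float(radii[i]), k)
            for k, i in enumerate(order)]


def estimate_background(frames) -> np.ndarray:
    """Pixel-wise maximum over the frame stack (>= 2 frames)."""
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a stack of at least two frames")
    return frames.max(axis=0)


def segment_cores(frame, background, cfg: CalibrationConfig,
                  roi_mask: np.ndarray | None = None) -> SegmentationResult:
    """Background-subtract, binarize, erode twice, filter components by area.

    The difference is ``background - frame`` so larvae (darker than the
    background) become positive.  Components of the eroded image with area
    inside the configured core bounds are returned as candidates.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    diff = background - frame
    binary = diff > cfg.binarize_threshold
    if roi_mask is not None:
        binary &= roi_mask
    eroded = ndimage.binary_erosion(binary, EROSION_STRUCTURE,
                                    iterations=cfg.erosion_iterations)
    labels, n = ndimage.label(eroded)
    candidates = []
    if n:
        areas = np.bincount(labels.ravel())[1:]
        lo, hi = cfg.core_area_min_px2, cfg.core_area_max_px2
        for i in np.nonzero((areas >= lo) & (areas <= hi))[0] + 1:
            ys, xs = np.nonzero(labels == i)
            candidates.append(CoreCandidate(
                centroid=np.array([xs.mean(), ys.mean()]),
                area=int(areas[i - 1]), pixels=(ys, xs)))
    return SegmentationResult(binary, eroded, candidates)


# ----------------------------------------------------------------------
def compute_heading(pixels: tuple[np.ndarray, np.ndarray],
                    prev_heading: float | None = None,
                    ) -> tuple[float, bool]:
    """Heading from second-order moments, head-forward by third-moment skew.

    The principal axis of the central second moments gives the body axis up
    to 180 degrees; the head+bladder end is denser than the trunk, so the
    third central moment along the axis points toward the thin (tail) side
    and the heading is taken opposite to it.  When the skew is too weak to
    decide, continuity with ``prev_heading`` is used.

    Returns (heading in [0, 2*pi), ok).  ``ok`` is False for a degenerate
    (isotropic) component, in which case ``prev_heading`` (or 0) is
    returned unchanged.
    """
    ys, xs = pixels
    if len(xs) < 3:
        return (prev_heading if prev_heading is not None else 0.0), False
    x = xs - xs.mean()
    y = ys - ys.mean()
    mu20, mu02, mu11 = (x * x).mean(), (y * y).mean(), (x * y).mean()
    aniso = np.hypot(mu20 - mu02, 2 * mu11)
    total = mu20 + mu02
    if total <= 0 or aniso / total < 0.05:
        return (prev_heading if prev_heading is not None else 0.0), False
    ang = 0.5 * np.arctan2(2 * mu11, mu20 - mu02)
    proj = x * np.cos(ang) + y * np.sin(ang)
    sigma = proj.std()
    skew = (proj ** 3).mean() / sigma ** 3 if sigma > 0 else 0.0
    if abs(skew) > 0.1:
        heading = ang + np.pi if skew > 0 else ang
    elif prev_heading is not None:
        heading = ang if abs(wrap_signed(ang - prev_heading)) <= np.pi / 2 else ang + np.pi
    else:
        heading = ang
    return float(wrap_angle(heading)), True


# ----------------------------------------------------------------------
def _predict(history: list[np.ndarray]) -> np.ndarray:
    """Constant-velocity prediction from the last two positions."""
    if len(history) >= 2:
        return history[-1] + (history[-1] - history[-2])
    return history[-1]


def assign_identities(candidates: list[CoreCandidate],
                      previous: dict[int, list[np.ndarray]],
                      frame: int) -> tuple[dict[int, LarvaState], list[tuple[int, int]]]:
    """Match larvae to candidate cores, greedy in increasing distance.

    ``previous`` maps larva id to its positions over the last (up to two)
    frames.  Unmatched larvae carry their last position with ``valid=False``.
    Pairs of larvae whose *nearest* candidate coincides are reported as
    collisions.
    """
    ids = sorted(previous)
    pred = {i: _predict(previous[i]) for i in ids}
    collisions: list[tuple[int, int]] = []
    if candidates:
        nearest = {}
        for i in ids:
            d = [np.hypot(*(c.centroid - pred[i])) for c in candidates]
            nearest[i] = int(np.argmin(d))
        for a_idx, a in enumerate(ids):
            for b in ids[a_idx + 1:]:
                if nearest[a] == nearest[b]:
                    collisions.append((a, b))

    states: dict[int, LarvaState] = {}
    taken: set[int] = set()
    # greedy over all (distance, larva, candidate), ties by lower larva id
    pairs = sorted(
        (np.hypot(*(c.centroid - pred[i])), i, j)
        for i in ids for j, c in enumerate(candidates))
    matched: dict[int, int] = {}
    for d, i, j in pairs:
        if i in matched or j in taken:
            continue
        matched[i] = j
        taken.add(j)
    for i in ids:
        if i in matched:
            c = candidates[matched[i]]
            states[i] = LarvaState(i, frame, c.centroid.copy(), 0.0, True)
        else:
            states[i] = LarvaState(i, frame, previous[i][-1].copy(), 0.0, False)
    for a, b in collisions:
        states[a].collision_with = b
        states[b].collision_with = a
    return states, collisions


class IdentityTracker:
    """Per-well identity bookkeeping across frames.

    Frame 0 seeds identities by arbitrary (candidate-order) labelling;
    velocity is taken as zero for frame 1.  Headings are smoothed only by
    the continuity rule inside :func:`compute_heading`.
    """

    def __init__(self, n_larvae: int):
        self.n_larvae = n_larvae
        self.history: dict[int, list[np.ndarray]] = {}
        self.headings: dict[int, float] = {}

    def step(self, frame: int, candidates: list[CoreCandidate],
             ) -> tuple[dict[int, LarvaState], list[tuple[int, int]]]:
        if not self.history:
            if len(candidates) < self.n_larvae:
                raise RuntimeError(
                    f"frame {frame}: found {len(candidates)} cores for "
                    f"{self.n_larvae} larvae; cannot seed identities")
            for i in range(self.n_larvae):
                self.history[i] = [candidates[i].centroid.copy()]
            states = {i: LarvaState(i, frame, candidates[i].centroid.copy(),
                                    0.0, True) for i in range(self.n_larvae)}
            collisions: list[tuple[int, int]] = []
        else:
            states, collisions = assign_identities(candidates, self.history, frame)
            for i, st in states.items():
                self.history[i].append(st.position.copy())
                self.history[i] = self.history[i][-2:]
        # headings for matched larvae
        cand_by_pos = {tuple(np.round(c.centroid, 6)): c for c in candidates}
        for i, st in states.items():
            if st.valid:
                c = cand_by_pos.get(tuple(np.round(st.position, 6)))
                prev = self.headings.get(i)
                if c is not None:
                    heading, ok = compute_heading(c.pixels, prev)
                else:
                    heading, ok = (prev if prev is not None else 0.0), False
                st.heading = heading
                self.headings[i] = heading
            else:
                st.heading = self.headings.get(i, 0.0)
        return states, collisions
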