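"""Per-movement global kinematic parameters and tail-curvature kymographs.

Global parameters per detected movement: oscillation count, mean tail-beat
frequency (TBF), duration, heading direction range (heading re-zeroed at
movement onset), distance traveled (path length of the core) and average
speed (distance / duration).

The curvature kymograph evaluates, per frame of a movement, the unsigned
curvature of the spline-fitted tail midline

    c = |x' y'' - y' x''| / (x'^2 + y'^2)^(3/2)

with derivatives taken along the arc-length parameter, on a fixed grid of
normalized arc positions from head (0) to tip (1), in 1/mm.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import interpolate, signal

from ._geom import arc_lengths
from .bouts import MovementEvent
from .calibration import CalibrationConfig

__all__ = ["GlobalParams", "CurvatureKymograph", "compute_global_params",
           "count_oscillations", "midline_curvature", "compute_curvature"]


@dataclasses.dataclass
class GlobalParams:
    oscillations: float
    tbf_hz: float
    duration_ms: float
    heading_range_deg: float
    distance_mm: float
    speed_mm_s: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class CurvatureKymograph:
    values: np.ndarray          # (n_frames, n_positions), 1/mm, >= 0
    positions: np.ndarray       # normalized arc positions, 0 head .. 1 tip
    valid: np.ndarray           # per-frame flag


# ----------------------------------------------------------------------
def count_oscillations(bend_deg: np.ndarray, cfg: CalibrationConfig) -> float:
    """Half-beat extrema above the noise floor, two extrema per oscillation."""
    bend = np.asarray(bend_deg, dtype=float)
    thr = cfg.oscillation_min_peak_deg
    peaks, _ = signal.find_peaks(bend, height=thr)
    troughs, _ = signal.find_peaks(-bend, height=thr)
    return (len(peaks) + len(troughs)) / 2.0


def compute_global_params(event: MovementEvent, trace: np.ndarray,
                          track: np.ndarray, heading: np.ndarray,
                          cfg: CalibrationConfig) -> GlobalParams:
    """Global parameters for one movement.

    ``trace`` (deg), ``track`` ((T, 2) px) and ``heading`` (rad) cover the
    whole recording; the event's frame span indexes into them.
    """
    if event.n_frames < 2:
        raise ValueError("event shorter than 2 frames")
    s, e = event.start, event.end
    if e >= len(trace) or e >= len(track) or e >= len(heading):
        raise ValueError("event extends past the trace/track")
    seg = np.asarray(trace, dtype=float)[s:e + 1]
    duration_s = event.n_frames / cfg.frame_rate_hz
    osc = count_oscillations(seg, cfg)
    tbf = osc / duration_s
    hdg = np.unwrap(np.asarray(heading, dtype=float)[s:e + 1])
    hdg = hdg - hdg[0]
    heading_range = float(np.rad2deg(hdg.max() - hdg.min()))
    steps = np.diff(np.asarray(track, dtype=float)[s:e + 1], axis=0)
    distance_mm = cfg.to_mm(float(np.hypot(steps[:, 0], steps[:, 1]).sum()))
    return GlobalParams(
        oscillations=osc, tbf_hz=tbf, duration_ms=duration_s * 1000.0,
        heading_range_deg=heading_range, distance_mm=distance_mm,
        speed_mm_s=distance_mm / duration_s)


# ----------------------------------------------------------------------
def midline_curvature(points: np.ndarray, cfg: CalibrationConfig,
                      positions: np.ndarray | None = None,
                      smooth_px: float = 0.0) -> np.ndarray:
    """Unsigned curvature (1/mm) of one midline on normalized arc positions.

    The midline is fitted with a cubic spline parameterized by arc length;
    the Cartesian curvature formula is evaluated at the requested
    positions.  Degenerate midlines (straight lines collapse to zero
    curvature; fewer than 5 points raise).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 5:
        raise ValueError("need at least 5 midline points")
    if positions is None:
        positions = np.linspace(0.0, 1.0, cfg.curvature_positions)
    s = arc_lengths(pts)
    if s[-1] == 0:
        return np.zeros(len(positions))
    u = s / s[-1]
    # collapse duplicate parameter values, splprep requires strict increase
    keep = np.concatenate([[True], np.diff(u) > 1e-12])
    try:
        (tck, _) = interpolate.splprep([pts[keep, 0], pts[keep, 1]], u=u[keep],
                                       s=len(pts) * smooth_px ** 2, k=3)
    except Exception:
        return np.zeros(len(positions))
    d1 = np.column_stack(interpolate.splev(positions, tck, der=1))
    d2 = np.column_stack(interpolate.splev(positions, tck, der=2))
    num = np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    den = (d1[:, 0] ** 2 + d1[:, 1] ** 2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        c_px = np.where(den > 0, num / den, 0.0)
    return c_px / cfg.pixel_size_mm


def compute_curvature(midlines: list, cfg: CalibrationConfig,
                      ) -> CurvatureKymograph:
    """Curvature kymograph over the midlines of one movement.

    ``midlines`` is a list of :class:`~larvatrack.tail.TailMidline` (or
    (n, 2) arrays); rows for degenerate midlines are zero with the frame
    flagged invalid.
    """
    positions = np.linspace(0.0, 1.0, cfg.curvature_positions)
    values = np.zeros((len(midlines), len(positions)))
    valid = np.zeros(len(midlines), dtype=bool)
    for i, m in enumerate(midlines):
        pts = getattr(m, "points", m)
        try:
            values[i] = midline_curvature(pts, cfg, positions)
            valid[i] = True
        except ValueError:
            pass
    return CurvatureKymograph(values, positions, valid)
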