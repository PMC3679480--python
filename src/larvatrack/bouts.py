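"""Detection of discrete movement events from the bend-angle trace.

A frame is "active" when the tail-bending angle deviates from the running
mean over the ten surrounding frames by more than the configured angle
step.  Maximal runs of active frames become candidate events, events closer
than the merge gap are fused, and candidates are rejected unless the core
displaced enough, the bend-angle range is large enough, and (when eroded
masks are supplied) the eroded image changed by at least the configured
number of pixels between consecutive frames.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .calibration import CalibrationConfig

__all__ = ["MovementEvent", "detect_movements", "merge_events", "active_frames"]


@dataclasses.dataclass
class MovementEvent:
    larva_id: int
    well: int
    start: int                  # frame, inclusive
    end: int                    # frame, inclusive
    label: str | None = None
    params: dict = dataclasses.field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1


def _surrounding_mean(trace: np.ndarray, window: int) -> np.ndarray:
    """Mean over the ``window`` surrounding frames (half before, half
    after, excluding the current frame); boundary frames use what exists."""
    n = len(trace)
    half = window // 2
    c = np.concatenate([[0.0], np.cumsum(trace)])
    out = np.empty(n)
    for i in range(n):
        lo = max(i - half, 0)
        hi = min(i + half + 1, n)
        total = c[hi] - c[lo] - trace[i]
        count = hi - lo - 1
        out[i] = total / count if count > 0 else trace[i]
    return out


def active_frames(trace: np.ndarray, cfg: CalibrationConfig) -> np.ndarray:
    mean = _surrounding_mean(np.asarray(trace, dtype=float), cfg.move_window_frames)
    return np.abs(trace - mean) > cfg.move_angle_delta_deg


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def merge_events(spans: list[tuple[int, int]], cfg: CalibrationConfig,
                 ) -> list[tuple[int, int]]:
    """Fuse events separated by less than the merge gap (idempotent)."""
    if not spans:
        return []
    gap_frames = cfg.merge_gap_frames
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if (s - merged[-1][1] - 1) < gap_frames:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def detect_movements(trace: np.ndarray, track: np.ndarray | None,
                     cfg: CalibrationConfig,
                     eroded_change: np.ndarray | None = None,
                     larva_id: int = 0, well: int = 0,
                     ) -> list[MovementEvent]:
    """Segment one larva's cleaned bend-angle trace into movement events.

    Parameters
    ----------
    trace
        Cleaned bend-angle trace, degrees, one value per frame.
    track
        (T, 2) core positions in px, or None to skip the displacement test.
    eroded_change
        Per frame-pair pixel-change counts of the eroded mask (length T-1),
        or None to skip that test.
    """
    trace = np.asarray(trace, dtype=float)
    if track is not None:
        track = np.asarray(track, dtype=float)
        if len(track) != len(trace):
            raise ValueError("trace and track lengths differ")
    if eroded_change is not None and len(eroded_change) != len(trace) - 1:
        raise ValueError("eroded_change must have one entry per frame pair")

    spans = merge_events(_runs(active_frames(trace, cfg)), cfg)
    events = []
    for s, e in spans:
        seg = trace[s:e + 1]
        if seg.max() - seg.min() <= cfg.min_angle_range_deg:
            continue
        if track is not None:
            disp = cfg.to_mm(float(np.hypot(*(track[e] - track[s]))))
            if disp <= cfg.min_displacement_mm:
                continue
        if eroded_change is not None:
            changes = np.asarray(eroded_change)[s:max(e, s + 1)]
            if changes.size and changes.max() < cfg.min_eroded_pixel_change:
                continue
        events.append(MovementEvent(larva_id, well, int(s), int(e)))
    return events
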