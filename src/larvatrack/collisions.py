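"""Separating larvae in contact.

Two mechanisms, chosen by the distance between the two cores:

* merged *cores* are recovered by repeated erosion of the region of
  interest until at least two components emerge;
* merged *full bodies* (component area above the contact threshold) are
  split either by an optimal straight cut (cores closer than the
  line-vs-intensity threshold) or by raising the binarization threshold
  until two bodies, each containing one head centre, separate — the thin
  caudal tail is paler than the head, so a higher threshold peels
  overlapping tails apart first.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .calibration import CalibrationConfig
from .tracking import EROSION_STRUCTURE

__all__ = ["CollisionEvent", "resolve_merged_cores", "separate_bodies"]


@dataclasses.dataclass
class CollisionEvent:
    frame: int
    larva_a: int
    larva_b: int
    method: str       # 'erosion' | 'line' | 'intensity' | 'unresolved'


# ----------------------------------------------------------------------
def resolve_merged_cores(roi_binary: np.ndarray, cfg: CalibrationConfig,
                         max_iterations: int = 10, min_area: int = 4,
                         ) -> list[np.ndarray] | None:
    """Erode a merged-core ROI until >= 2 cores emerge.

    Returns the component centroids (x, y) in ROI coordinates, or None if
    the blob never splits within the iteration cap (the larvae cannot be
    tracked for this frame).
    """
    work = np.asarray(roi_binary, dtype=bool)
    for _ in range(max_iterations):
        work = ndimage.binary_erosion(work, EROSION_STRUCTURE)
        labels, n = ndimage.label(work)
        if n == 0:
            return None
        areas = np.bincount(labels.ravel())[1:]
        keep = np.nonzero(areas >= min_area)[0] + 1
        if len(keep) >= 2:
            cents = []
            for i in keep:
                ys, xs = np.nonzero(labels == i)
                cents.append(np.array([xs.mean(), ys.mean()]))
            return cents
    return None


# ----------------------------------------------------------------------
def _components_for_heads(mask: np.ndarray, heads: np.ndarray,
                          min_area: int = 0) -> list[np.ndarray] | None:
    """Masks of the components containing each head, or None if any head is
    on background, two heads share a component, or a component is smaller
    than ``min_area`` (a few stray pixels are not a body)."""
    labels, n = ndimage.label(mask)
    if n < 2:
        return None
    found = []
    for hx, hy in heads:
        x, y = int(round(hx)), int(round(hy))
        if not (0 <= y < mask.shape[0] and 0 <= x < mask.shape[1]):
            return None
        lab = labels[y, x]
        if lab == 0:
            # tolerate 1-px rounding: look at the 3x3 neighbourhood
            ys = slice(max(y - 1, 0), y + 2)
            xs = slice(max(x - 1, 0), x + 2)
            vals = labels[ys, xs]
            vals = vals[vals > 0]
            if vals.size == 0:
                return None
            lab = int(np.bincount(vals).argmax())
        found.append(int(lab))
    if len(set(found)) != len(found):
        return None
    masks = [labels == lab for lab in found]
    if min_area and any(m.sum() < min_area for m in masks):
        return None
    return masks


def _line_separation(mask: np.ndarray, heads: np.ndarray,
                     cfg: CalibrationConfig,
                     ) -> tuple[np.ndarray, np.ndarray] | None:
    """Cut the blob with the straight line maximizing the summed areas of
    the two head-bearing components; ties broken by fewest erased pixels."""
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    mid = heads.mean(axis=0)
    axis = heads[1] - heads[0]
    norm = np.hypot(*axis)
    axis = axis / norm if norm > 0 else np.array([1.0, 0.0])
    half_span = max(int(np.ceil(norm / 2)) + 2, 4)

    best = None   # (total_area, -erased, masks)
    for ang in np.linspace(0.0, np.pi, cfg.line_angles, endpoint=False):
        d = np.array([np.cos(ang), np.sin(ang)])
        for off in range(-half_span, half_span + 1):
            p0 = mid + off * axis
            # signed distance of each foreground pixel to the cutting line
            dist = np.abs((pts[:, 0] - p0[0]) * d[1] - (pts[:, 1] - p0[1]) * d[0])
            erase = dist <= 0.75
            n_erased = int(erase.sum())
            if n_erased == 0 or n_erased == len(pts):
                continue
            cut = mask.copy()
            cut[ys[erase], xs[erase]] = False
            comps = _components_for_heads(cut, heads)
            if comps is None:
                continue
            total = int(comps[0].sum() + comps[1].sum())
            key = (total, -n_erased)
            if best is None or key > best[0]:
                best = (key, (comps[0], comps[1]))
    return None if best is None else best[1]


def _intensity_separation(grayscale: np.ndarray, background: np.ndarray,
                          mask: np.ndarray, heads: np.ndarray,
                          cfg: CalibrationConfig,
                          ) -> tuple[np.ndarray, np.ndarray] | None:
    """Raise the binarization threshold stepwise until two full bodies,
    each containing one head centre, emerge."""
    diff = np.asarray(background, dtype=float) - np.asarray(grayscale, dtype=float)
    t = cfg.binarize_threshold
    while t <= cfg.intensity_cap:
        t += cfg.intensity_step
        cut = (diff > t) & mask
        comps = _components_for_heads(cut, heads,
                                      min_area=int(cfg.core_area_min_px2))
        if comps is not None:
            return comps[0], comps[1]
    return None


def separate_bodies(mask: np.ndarray, heads, grayscale: np.ndarray,
                    background: np.ndarray, cfg: CalibrationConfig,
                    ) -> tuple[np.ndarray, np.ndarray, str] | None:
    """Split a merged full-body component into two, one per head centre.

    Parameters
    ----------
    mask
        Boolean mask of the merged component (area above the contact
        threshold); both head centres must lie inside it.
    heads
        (2, 2) array of the two head-centre positions (x, y).

    Returns
    -------
    (body_a, body_b, method) with disjoint boolean masks ordered like
    ``heads``, or None when no cut or threshold separates the larvae
    (tails are then carried from the previous frame).
    """
    heads = np.asarray(heads, dtype=float)
    if heads.shape != (2, 2):
        raise ValueError("exactly two head centres required")
    for hx, hy in heads:
        if not mask[int(round(hy)), int(round(hx))]:
            raise ValueError(f"head centre ({hx:.1f}, {hy:.1f}) outside the component")
    # work on the bounding box of the component for speed
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    sub = mask[y0:y1, x0:x1]
    heads_sub = heads - [x0, y0]

    dist_mm = cfg.to_mm(float(np.hypot(*(heads[1] - heads[0]))))
    if dist_mm < cfg.contact_line_vs_threshold_mm:
        out = _line_separation(sub, heads_sub, cfg)
        method = "line"
    else:
        out = _intensity_separation(np.asarray(grayscale)[y0:y1, x0:x1],
                                    np.asarray(background)[y0:y1, x0:x1],
                                    sub, heads_sub, cfg)
        method = "intensity"
    if out is None:
        return None
    full = []
    for sub_mask in out[:2]:
        m = np.zeros_like(mask)
        m[y0:y1, x0:x1] = sub_mask
        full.append(m)
    return full[0], full[1], method
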