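"""Stage orchestration and tabular I/O.

The stages exchange flat CSV tables (one row per frame-larva or per
movement) plus JSON for nested structures (ground truth, the classifier
model, run manifests), so each stage can be re-run from the previous
stage's files:

    simulate -> frames/*.png + truth.json
    track    -> track.csv (frame, well, larva_id, x, y, heading_rad, valid,
                eroded_change) + tail.csv (midline points, tail length,
                bend angle) + collisions.csv
    detect   -> movements.csv (+ global kinematic parameters)
    classify -> movements.csv with a label column (model from fit)
    interact -> transition_index.csv + interactions.json
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import bouts, collisions, kinematics, tail, tracking
from .calibration import CalibrationConfig
from .tracking import WellROI

__all__ = [
    "WellTrackResult", "track_frames", "movements_from_tables",
    "write_manifest", "read_frames", "write_frames",
    "track_tables", "interactions_summary",
]


@dataclasses.dataclass
class WellTrackResult:
    well: int
    n_larvae: int
    positions: dict[int, np.ndarray]      # larva -> (T, 2) px
    headings: dict[int, np.ndarray]       # larva -> (T,) rad
    valid: dict[int, np.ndarray]          # larva -> (T,) bool (core)
    midlines: dict[int, list]             # larva -> [TailMidline] per frame
    bend_deg: dict[int, np.ndarray]       # raw per-frame bend angle
    tail_valid: dict[int, np.ndarray]
    eroded_change: dict[int, np.ndarray]  # larva -> (T-1,) pixel changes
    collision_log: list[collisions.CollisionEvent]


def _pixel_set(candidate: tracking.CoreCandidate | None) -> set:
    if candidate is None:
        return set()
    ys, xs = candidate.pixels
    return set(zip(ys.tolist(), xs.tolist()))


def track_frames(frames: np.ndarray, well: WellROI, n_larvae: int,
                 cfg: CalibrationConfig,
                 background: np.ndarray | None = None) -> WellTrackResult:
    """Track cores and tails for one well over a frame stack."""
    n = len(frames)
    if background is None:
        background = tracking.estimate_background(frames)
    roi = well.mask(frames[0].shape)
    tracker = tracking.IdentityTracker(n_larvae)
    ids = list(range(n_larvae))
    res = WellTrackResult(
        well=well.index, n_larvae=n_larvae,
        positions={i: np.zeros((n, 2)) for i in ids},
        headings={i: np.zeros(n) for i in ids},
        valid={i: np.zeros(n, dtype=bool) for i in ids},
        midlines={i: [] for i in ids},
        bend_deg={i: np.zeros(n) for i in ids},
        tail_valid={i: np.zeros(n, dtype=bool) for i in ids},
        eroded_change={i: np.zeros(max(n - 1, 0)) for i in ids},
        collision_log=[])
    prev_mid: dict[int, tail.TailMidline | None] = {i: None for i in ids}
    prev_pixels: dict[int, set] = {i: set() for i in ids}
    core_area: dict[int, float] = {i: cfg.core_area_min_px2 for i in ids}

    for f in range(n):
        seg = tracking.segment_cores(frames[f], background, cfg, roi)
        states, collide = tracker.step(f, seg.candidates)

        # collision resolution on merged cores: erode the shared blob's ROI
        for a, b in collide:
            shared = min(seg.candidates, key=lambda c: float(np.hypot(
                *(c.centroid - states[a].position))), default=None)
            method = "unresolved"
            if shared is not None:
                ys, xs = shared.pixels
                y0, y1 = ys.min() - 6, ys.max() + 7
                x0, x1 = xs.min() - 6, xs.max() + 7
                roi_bin = seg.eroded[max(y0, 0):y1, max(x0, 0):x1]
                cores = collisions.resolve_merged_cores(roi_bin, cfg)
                if cores is not None and len(cores) >= 2:
                    offs = np.array([max(x0, 0), max(y0, 0)], dtype=float)
                    cands = [c + offs for c in cores]
                    for i in (a, b):
                        pred = tracker.history[i][-1]
                        j = int(np.argmin([np.hypot(*(c - pred)) for c in cands]))
                        states[i].position = cands.pop(j) if len(cands) > 1 else cands[0]
                        states[i].valid = True
                        tracker.history[i][-1] = states[i].position.copy()
                    method = "erosion"
                else:
                    for i in (a, b):
                        states[i].valid = False
            res.collision_log.append(collisions.CollisionEvent(f, a, b, method))

        cand_used: dict[int, tracking.CoreCandidate | None] = {}
        for i, st in states.items():
            cand = None
            if st.valid and seg.candidates:
                cand = min(seg.candidates, key=lambda c: float(np.hypot(
                    *(c.centroid - st.position))))
                if np.hypot(*(cand.centroid - st.position)) > 1.0:
                    cand = None
            cand_used[i] = cand
            if cand is not None:
                core_area[i] = cand.area
            res.positions[i][f] = st.position
            res.headings[i][f] = st.heading
            res.valid[i][f] = st.valid
            if f > 0:
                cur = _pixel_set(cand)
                res.eroded_change[i][f - 1] = len(cur ^ prev_pixels[i])
                prev_pixels[i] = cur
            else:
                prev_pixels[i] = _pixel_set(cand)

        # tails, with full-body contact separation when two larvae touch
        handled: set[int] = set()
        merged_pairs = [(a, b) for a, b in collide]
        for a, b in list(merged_pairs):
            st_a, st_b = states[a], states[b]
            if not (st_a.valid and st_b.valid):
                continue
            try:
                body = tail.extract_full_body(seg.binary, st_a.position)
            except tail.BodyMissingError:
                continue
            if body.sum() <= cfg.contact_area_px2:
                continue
            heads = np.array([
                tail.head_center_from_core(st.position, st.heading, core_area[i])
                for i, st in ((a, st_a), (b, st_b))])
            hx = np.round(heads).astype(int)
            if not all(body[y, x] for x, y in hx):
                continue
            out = collisions.separate_bodies(body, heads, frames[f],
                                             background, cfg)
            if out is None:
                res.collision_log.append(
                    collisions.CollisionEvent(f, a, b, "unresolved"))
                continue
            for i, m in ((a, out[0]), (b, out[1])):
                mid = tail.track_tail(m, states[i], core_area[i], cfg, prev_mid[i])
                _record_tail(res, prev_mid, i, f, mid, states[i])
                handled.add(i)
            res.collision_log.append(
                collisions.CollisionEvent(f, a, b, out[2]))

        for i, st in states.items():
            if i in handled:
                continue
            mid = tail.track_tail(seg.binary, st, core_area[i], cfg, prev_mid[i])
            _record_tail(res, prev_mid, i, f, mid, st)
    return res


def _record_tail(res: WellTrackResult, prev_mid: dict, i: int, f: int,
                 mid: tail.TailMidline, st: tracking.LarvaState) -> None:
    prev_mid[i] = mid
    res.midlines[i].append(mid)
    try:
        res.bend_deg[i][f] = tail.compute_bend_angle(mid, st)
    except ValueError:
        res.bend_deg[i][f] = res.bend_deg[i][f - 1] if f else 0.0
    res.tail_valid[i][f] = mid.valid


# ----------------------------------------------------------------------
def track_tables(result: WellTrackResult, cfg: CalibrationConfig,
                 ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Flatten a WellTrackResult into (track, tail, collisions) tables."""
    rows, tail_rows = [], []
    n = len(next(iter(result.positions.values())))
    for i in sorted(result.positions):
        for f in range(n):
            x, y = result.positions[i][f]
            rows.append({
                "frame": f, "well": result.well, "larva_id": i,
                "x": x, "y": y, "heading_rad": result.headings[i][f],
                "valid": bool(result.valid[i][f]),
                "eroded_change": (result.eroded_change[i][f - 1] if f else 0.0),
            })
            mid = result.midlines[i][f]
            row = {"frame": f, "well": result.well, "larva_id": i}
            for k, (px, py) in enumerate(mid.points):
                row[f"x{k}"] = px
                row[f"y{k}"] = py
            row["tail_length_mm"] = mid.tail_length_mm
            row["bend_angle_deg"] = result.bend_deg[i][f]
            row["valid"] = bool(result.tail_valid[i][f])
            tail_rows.append(row)
    col_rows = [{"frame": c.frame, "well": result.well, "larva_a": c.larva_a,
                 "larva_b": c.larva_b, "method": c.method}
                for c in result.collision_log]
    return (pd.DataFrame(rows), pd.DataFrame(tail_rows),
            pd.DataFrame(col_rows, columns=["frame", "well", "larva_a",
                                            "larva_b", "method"]))


def movements_from_tables(track_df: pd.DataFrame, tail_df: pd.DataFrame,
                          cfg: CalibrationConfig) -> pd.DataFrame:
    """Detect movements and compute global parameters from stage tables."""
    out = []
    for (well, larva), g in track_df.groupby(["well", "larva_id"]):
        g = g.sort_values("frame")
        gt = tail_df[(tail_df["well"] == well)
                     & (tail_df["larva_id"] == larva)].sort_values("frame")
        trace = tail.clean_trace(gt["bend_angle_deg"].to_numpy(),
                                 gt["valid"].to_numpy(dtype=bool), cfg)
        track = g[["x", "y"]].to_numpy()
        heading = g["heading_rad"].to_numpy()
        changes = g["eroded_change"].to_numpy()[1:] if "eroded_change" in g else None
        events = bouts.detect_movements(trace, track, cfg, changes,
                                        larva_id=int(larva), well=int(well))
        for ev in events:
            gp = kinematics.compute_global_params(ev, trace, track, heading, cfg)
            out.append({
                "well": int(well), "larva_id": int(larva),
                "start_frame": ev.start, "end_frame": ev.end,
                "start_s": ev.start / cfg.frame_rate_hz,
                "end_s": ev.end / cfg.frame_rate_hz,
                "x_mm": cfg.to_mm(track[ev.start, 0]),
                "y_mm": cfg.to_mm(track[ev.start, 1]),
                **gp.to_dict(),
            })
    cols = ["well", "larva_id", "start_frame", "end_frame", "start_s",
            "end_s", "x_mm", "y_mm", "oscillations", "tbf_hz", "duration_ms",
            "heading_range_deg", "distance_mm", "speed_mm_s"]
    return pd.DataFrame(out, columns=cols)


def interactions_summary(movements: pd.DataFrame, cfg: CalibrationConfig,
                         t_edges=(0.0, 1.0, 2.0, 4.0),
                         d_edges=(0.0, 5.0, 10.0, 20.0),
                         n_permutations: int = 50, seed: int = 0,
                         ) -> tuple[pd.DataFrame, dict]:
    """Long-format transition grids and permutation summaries."""
    from . import transitions as tr
    df = movements.rename(columns={"start_s": "t_s"})[
        ["well", "larva_id", "t_s", "x_mm", "y_mm", "label"]]
    long_rows = []
    summary: dict = {"variants": {}}
    for variant in ("same", "different"):
        mat, counts = tr.transition_index(df, variant)
        summary["variants"][variant] = {
            "transition_index": mat.to_dict(), "pair_counts": counts.to_dict()}
        grids = tr.windowed_index(df, t_edges, d_edges, variant,
                                  min_count=cfg.min_pair_count)
        for g in grids:
            for ti in range(len(g.t_edges) - 1):
                for di in range(len(g.d_edges) - 1):
                    long_rows.append({
                        "pair": f"{g.pair[0]}-{g.pair[1]}", "variant": variant,
                        "t_lo": g.t_edges[ti], "t_hi": g.t_edges[ti + 1],
                        "d_lo": g.d_edges[di], "d_hi": g.d_edges[di + 1],
                        "I": g.index[ti, di], "n_pairs": int(g.counts[ti, di]),
                    })
        for b in tr.CLASSES:
            res = tr.permutation_test(df, (b, b), variant, t_edges, d_edges,
                                      n_permutations=n_permutations, seed=seed,
                                      min_count=cfg.min_pair_count)
            summary["variants"][variant][f"I_max_{b}{b}"] = {
                "observed": res.observed, "p_ttest": res.p_ttest,
                "p_exceedance": res.p_exceedance,
                "null_mean": res.null_mean, "null_sd": res.null_sd,
            }
    return pd.DataFrame(long_rows), summary


# ----------------------------------------------------------------------
def write_frames(frames: np.ndarray, out_dir: str | Path) -> list[str]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, fr in enumerate(frames):
        name = f"frame_{i:06d}.png"
        iio.imwrite(out_dir / name, fr)
        names.append(name)
    return names


def read_frames(path: str | Path) -> np.ndarray:
    """Read a numbered image sequence (directory) or a video container."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png")) or sorted(path.glob("*.tif"))
        if not files:
            raise FileNotFoundError(f"no frames found in {path}")
        return np.stack([iio.imread(f) for f in files])
    return np.asarray(iio.imread(path))


def write_manifest(out_dir: str | Path, stage: str, inputs: list[str],
                   cfg: CalibrationConfig, seed: int | None,
                   outputs: dict[str, int]) -> Path:
    """Append one stage record to the run manifest (written atomically)."""
    out_dir = Path(out_dir)
    path = out_dir / "manifest.json"
    manifest = {"stages": []}
    if path.exists():
        manifest = json.loads(path.read_text())
    manifest["stages"].append({
        "stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": inputs, "seed": seed, "config": cfg.to_dict(),
        "outputs": outputs,
    })
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=1))
    os.replace(tmp, path)
    return path
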