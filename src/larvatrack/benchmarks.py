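"""Self-contained validation experiments on synthetic fixtures.

Each function generates its own inputs with the fixture module, runs the
relevant pipeline stage end to end, and reports summary metrics as a plain
dict.  They are used both by the test suite and by the reproduction script,
so every reported number is recomputed from scratch at call time.

Problem sizes default to desk scale (a thousand frames, tens of crossings,
hundreds of planted events) — large enough for stable rates while keeping
a full run in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from . import bouts, classify as clf, collisions, kinematics, pipeline, synth, tail, tracking, transitions as tr
from ._geom import rotate
from .calibration import CalibrationConfig

__all__ = [
    "tracking_fidelity", "collision_resolution", "movement_detection",
    "curvature_oracle", "classifier_recovery", "transition_null",
    "transition_planted",
]

# the marginal maneuver frequencies observed in group recordings of
# wild-type larvae (S, T, E); used for label draws in the sequence fixtures
WT_MARGINALS = {"S": 0.35, "T": 0.48, "E": 0.16}


def _marginal_p() -> np.ndarray:
    p = np.array([WT_MARGINALS[c] for c in tr.CLASSES], dtype=float)
    return p / p.sum()


# ----------------------------------------------------------------------
def tracking_fidelity(cfg: CalibrationConfig, n_frames: int = 1000,
                      n_larvae: int = 7, seed: int = 0) -> dict:
    """Track a collision-free multi-larva video and score against truth.

    Reports identity switches (changes of the nearest-truth assignment per
    tracked larva), core position RMS error (px) and bend-angle RMS error
    (deg, cleaned trace vs. truth).
    """
    layout = synth.single_well_layout(n_larvae)
    script = synth.ping_pong_script(layout, n_frames, cfg)
    frames, gt = synth.render_video(cfg, layout, script, n_frames, seed=seed)
    well = tracking.WellROI(layout.wells[0].center, layout.wells[0].radius, 0)
    res = pipeline.track_frames(frames, well, n_larvae, cfg)

    gt_pos = np.stack([lv.core for lv in gt.larvae])          # (L, T, 2)
    switches = 0
    core_sq, bend_sq, n_pts = [], [], 0
    for i in sorted(res.positions):
        pos = res.positions[i]
        d = np.linalg.norm(gt_pos - pos[None], axis=2)         # (L, T)
        nearest = d.argmin(axis=0)
        switches += int((np.diff(nearest) != 0).sum())
        lv = gt.larvae[nearest[0]]
        core_sq.append(((pos - lv.core) ** 2).sum(axis=1))
        cleaned = tail.clean_trace(res.bend_deg[i], res.tail_valid[i], cfg)
        bend_sq.append((cleaned - lv.bend_deg) ** 2)
        n_pts += n_frames
    return {
        "n_frames": n_frames, "n_larvae": n_larvae,
        "identity_switches": switches,
        "core_rms_px": float(np.sqrt(np.concatenate(core_sq).mean())),
        "bend_rms_deg": float(np.sqrt(np.concatenate(bend_sq).mean())),
        "invalid_tail_fraction": float(np.mean(
            [1 - res.tail_valid[i].mean() for i in res.tail_valid])),
    }


# ----------------------------------------------------------------------
def _head_near(mask: np.ndarray, head: np.ndarray, r: int = 1) -> bool:
    x, y = int(round(head[0])), int(round(head[1]))
    return bool(mask[max(y - r, 0):y + r + 1, max(x - r, 0):x + r + 1].any())


CROSSING_GEOMETRIES = [
    # (angle between paths in deg, lateral offset in px); a uniform spread
    # of crossing angles from glancing to head-on
    (30, 6), (45, 0), (45, 8), (60, 0), (60, 10), (75, 5), (90, 0), (90, 8),
    (105, 5), (120, 0), (120, 8), (135, 6), (150, 0), (150, 6), (165, 8),
    (180, 6), (180, 8), (180, 10), (30, 10), (75, 10), (105, 10), (135, 10),
]


def collision_resolution(cfg: CalibrationConfig, n_frames: int = 240,
                         seed: int = 0, geometries=None) -> dict:
    """Score contact separation over scripted pairwise crossings.

    A contact frame is one where both larvae's full bodies merge into a
    component larger than the contact-area threshold.  A frame counts as
    resolved when the separation yields two disjoint components, each
    containing its larva's head centre (1-px rounding tolerance: the head
    centre is subpixel while components are pixel sets).
    """
    if geometries is None:
        geometries = CROSSING_GEOMETRIES
    n_events = contact = resolved = 0
    methods: dict[str, int] = {}
    for k, (angle, offset) in enumerate(geometries):
        layout = synth.crossing_layout(angle, offset)
        script = synth.crossing_script(cfg)
        frames, gt = synth.render_video(cfg, layout, script, n_frames,
                                        seed=seed + k)
        bg = frames.max(axis=0)
        event_contact = 0
        for f in range(n_frames):
            binary = (bg.astype(float) - frames[f]) > cfg.binarize_threshold
            heads = np.array([
                tail.head_center_from_core(lv.core[f], lv.heading[f], 60.0)
                for lv in gt.larvae])
            labels, _ = ndimage.label(binary)
            hl = [labels[int(round(h[1])), int(round(h[0]))] for h in heads]
            if hl[0] == 0 or hl[0] != hl[1]:
                continue
            mask = labels == hl[0]
            if mask.sum() <= cfg.contact_area_px2:
                continue
            event_contact += 1
            out = collisions.separate_bodies(mask, heads, frames[f], bg, cfg)
            if out is None:
                methods["unresolved"] = methods.get("unresolved", 0) + 1
                continue
            a, b, method = out
            methods[method] = methods.get(method, 0) + 1
            if (_head_near(a, heads[0]) and _head_near(b, heads[1])
                    and not (a & b).any()):
                resolved += 1
        contact += event_contact
        if event_contact:
            n_events += 1
    return {
        "n_crossing_events": n_events, "contact_frames": contact,
        "resolved_frames": resolved,
        "resolution_rate": resolved / contact if contact else float("nan"),
        "methods": methods,
    }


# ----------------------------------------------------------------------
def movement_detection(cfg: CalibrationConfig, n_traces: int = 20,
                       events_per_trace: int = 10, noise_sd: float = 0.3,
                       seed: int = 0) -> dict:
    """Detect planted events in noisy bend traces; report error rates.

    The larva's core advances during each planted event (as it does when
    the tail beats), so the displacement rejection rule is active.
    Matched boundaries are scored in ms.
    """
    rng = np.random.default_rng(seed)
    order = list(synth.ARCHETYPES)
    n_true = n_det = n_matched = 0
    start_err, end_err = [], []
    for rep in range(n_traces):
        sched = []
        t = 300.0
        for k in range(events_per_trace):
            arch = synth.ARCHETYPES[order[int(rng.integers(len(order)))]]
            sched.append((arch, t))
            t += arch.duration_ms + float(rng.uniform(450, 750))
        trace, events = synth.synth_bend_trace(
            sched, t + 300.0, noise_sd, seed=seed * 1009 + rep,
            frame_rate_hz=cfg.frame_rate_hz)
        track = np.zeros((len(trace), 2))
        x = 0.0
        in_event = np.zeros(len(trace), dtype=bool)
        for e in events:
            in_event[e.start:e.end + 1] = True
        for i in range(1, len(trace)):
            x += 0.3 if in_event[i] else 0.0
            track[i] = [x, 0.0]
        detected = bouts.detect_movements(trace, track, cfg)
        n_true += len(events)
        n_det += len(detected)
        used = set()
        for e in events:
            best = None
            for j, d in enumerate(detected):
                if j in used or d.start > e.end or d.end < e.start:
                    continue
                best = j
                break
            if best is not None:
                used.add(best)
                n_matched += 1
                d = detected[best]
                start_err.append(abs(d.start - e.start))
                end_err.append(abs(d.end - e.end))
    to_ms = 1000.0 / cfg.frame_rate_hz
    start_ms = np.asarray(start_err) * to_ms
    end_ms = np.asarray(end_err) * to_ms
    return {
        "n_planted": n_true, "n_detected": n_det, "n_matched": n_matched,
        "false_negative_rate": (n_true - n_matched) / n_true,
        "false_positive_rate": (n_det - n_matched) / max(n_det, 1),
        "boundary_within_15ms_fraction": float(np.mean(
            (start_ms <= 15.0) & (end_ms <= 15.0))) if len(start_ms) else 0.0,
        "start_err_ms_p95": float(np.percentile(start_ms, 95)) if len(start_ms) else np.nan,
        "end_err_ms_p95": float(np.percentile(end_ms, 95)) if len(end_ms) else np.nan,
    }


# ----------------------------------------------------------------------
def curvature_oracle(cfg: CalibrationConfig, radii_px=(5, 10, 20, 35, 50),
                     n_points: int = 30) -> dict:
    """Analytic checks: circular arcs, straight lines, rigid motions."""
    max_rel = 0.0
    for r in radii_px:
        th = np.linspace(0.3, 1.5, n_points)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        c = kinematics.midline_curvature(pts, cfg)
        expected = 1.0 / (r * cfg.pixel_size_mm)
        max_rel = max(max_rel, float(np.max(np.abs(c - expected) / expected)))
    straight = np.column_stack([np.linspace(0, 40, 12), np.zeros(12)])
    straight_max = float(kinematics.midline_curvature(straight, cfg).max())
    pts = np.column_stack([10 * np.cos(np.linspace(0.3, 1.5, n_points)),
                           10 * np.sin(np.linspace(0.3, 1.5, n_points))])
    base = kinematics.midline_curvature(pts, cfg)
    moved = kinematics.midline_curvature(
        rotate(pts, 0.83, origin=(3.0, -7.0)) + [11.3, -4.2], cfg)
    rigid_rel = float(np.max(np.abs(moved - base) / np.abs(base)))
    return {
        "circle_max_rel_err": max_rel,
        "straight_max_curvature": straight_max,
        "rigid_motion_max_rel_change": rigid_rel,
    }


# ----------------------------------------------------------------------
def _synthetic_labelled_movements(cfg: CalibrationConfig, n: int, seed: int,
                                  proportions: np.ndarray | None = None,
                                  ) -> tuple[list, list]:
    rng = np.random.default_rng(seed)
    if proportions is None:
        proportions = np.full(3, 1.0 / 3.0)
    feats, labels = [], []
    draws = rng.choice(list(tr.CLASSES), size=n, p=proportions)
    for k, label in enumerate(draws):
        trace, track, ev = synth.synth_movement(
            synth.ARCHETYPES[label], noise_sd=0.3,
            seed=int(rng.integers(2 ** 31)), cfg=cfg)
        mev = bouts.MovementEvent(0, 0, ev.start, ev.end)
        try:
            feats.append(clf.extract_features(mev, trace, track, cfg))
            labels.append(label)
        except clf.FeatureExtractionError:
            continue
    return feats, labels


def classifier_recovery(cfg: CalibrationConfig, n_train: int = 300,
                        n_test: int = 150, seed: int = 0) -> dict:
    """Train the two-stage categorizer on synthetic archetype movements and
    score it on a held-out draw."""
    f_tr, y_tr = _synthetic_labelled_movements(cfg, n_train, seed)
    f_te, y_te = _synthetic_labelled_movements(cfg, n_test, seed + 7919)
    model = clf.fit_model(f_tr, y_tr, cfg, seed)
    pred = [clf.classify(model, f) for f in f_te]
    acc = float(np.mean([p == y for p, y in zip(pred, y_te)]))
    per_class = {c: float(np.mean([p == y for p, y in zip(pred, y_te) if y == c]))
                 for c in tr.CLASSES}
    return {
        "n_train": len(y_tr), "n_test": len(y_te),
        "accuracy": acc, "per_class_accuracy": per_class,
        "raw_feature_dim": int(f_tr[0].raw.shape[0]),
        "n_principal_components": int(model.pca_components.shape[0]),
        "explained_variance": model.explained_variance,
    }


# ----------------------------------------------------------------------
def _iid_movements(cfg: CalibrationConfig, n: int, n_larvae: int,
                   seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    labels = rng.choice(list(tr.CLASSES), size=n, p=_marginal_p())
    return pd.DataFrame({
        "well": 0,
        "larva_id": rng.integers(0, n_larvae, n),
        "t_s": np.sort(rng.uniform(0.0, 0.45 * n, n)),
        "x_mm": rng.uniform(0.0, 22.0, n),
        "y_mm": rng.uniform(0.0, 22.0, n),
        "label": labels,
    })


def transition_null(cfg: CalibrationConfig, n: int = 10_000,
                    n_larvae: int = 7, seed: int = 0) -> dict:
    """All nine transition indices on i.i.d. maneuver sequences.

    Also reports the analytic Monte-Carlo standard error per cell so the
    deviation can be judged in sigma units.
    """
    df = _iid_movements(cfg, n, n_larvae, seed)
    out = {}
    p = dict(zip(tr.CLASSES, _marginal_p()))
    for variant in ("same", "different"):
        index, counts = tr.transition_index(df, variant)
        devs, sigmas = [], []
        for b1 in tr.CLASSES:
            row_n = counts.loc[b1].sum()
            for b2 in tr.CLASSES:
                i_val = index.loc[b1, b2]
                sd = np.sqrt((1 - p[b2]) / (row_n * p[b2])) if row_n else np.nan
                devs.append(abs(i_val - 1.0))
                sigmas.append(abs(i_val - 1.0) / sd if sd else np.nan)
        out[variant] = {
            "max_abs_deviation": float(np.nanmax(devs)),
            "max_sigma": float(np.nanmax(sigmas)),
            "index": index.to_dict(),
        }
    return {"n_movements": n, **out}


def _planted_chain(cfg: CalibrationConfig, n: int, seed: int,
                   enrichment: float = 3.0) -> pd.DataFrame:
    """Markov chain whose E->E conditional is ``enrichment`` times the
    stationary E marginal; movements 0.5 s apart, all within a few mm."""
    rng = np.random.default_rng(seed)
    pi_e = WT_MARGINALS["E"] / sum(WT_MARGINALS.values())
    a = enrichment * pi_e                       # P(E | prev E)
    b = (pi_e - enrichment * pi_e ** 2) / (1 - pi_e)   # P(E | prev not E)
    p_st = np.array([WT_MARGINALS["S"], WT_MARGINALS["T"]])
    p_st = p_st / p_st.sum()
    labels = []
    prev = None
    for _ in range(n):
        pe = a if prev == "E" else b
        if rng.random() < pe:
            cur = "E"
        else:
            cur = "S" if rng.random() < p_st[0] else "T"
        labels.append(cur)
        prev = cur
    return pd.DataFrame({
        "well": 0, "larva_id": 0, "t_s": np.arange(n) * 0.5,
        "x_mm": rng.uniform(0.0, 3.0, n), "y_mm": rng.uniform(0.0, 3.0, n),
        "label": labels,
    })


def transition_planted(cfg: CalibrationConfig, n: int = 20_000,
                       seed: int = 0, n_permutations: int = 50) -> dict:
    """Recover a planted 3x E->E enrichment and its permutation p-value."""
    df = _planted_chain(cfg, n, seed)
    t_edges, d_edges = [0.0, 1.0, 2.0], [0.0, 5.0, 10.0]
    grid = tr.windowed_index(df, t_edges, d_edges, "same", pair=("E", "E"),
                             min_count=cfg.min_pair_count)[0]
    res = tr.permutation_test(df, ("E", "E"), "same", t_edges, d_edges,
                              n_permutations=n_permutations, seed=seed + 1,
                              min_count=cfg.min_pair_count)
    # the enriched cell: consecutive pairs are 0.5 s apart -> first cell
    all_pairs = tr.windowed_pairs(df, "same", t_edges[1])
    n_pairs = len(all_pairs)
    return {
        "n_movements": n, "n_pairs_first_window": n_pairs,
        "n_first_is_E_pairs": int(grid.counts[0].sum()),
        "i_max": grid.i_max, "p_ttest": res.p_ttest,
        "p_exceedance": res.p_exceedance, "null_mean": res.null_mean,
        "null_sd": res.null_sd,
    }
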