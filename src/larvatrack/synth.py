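"""Synthetic well recordings with exact ground truth.

Real recordings of this kind image dark larvae on a bright, homogeneously lit
plate: a rigid head+swim-bladder blob and a tapering flexible tail, swimming
in discrete beat-and-glide bouts inside circular wells.  This module renders
such scenes frame by frame and returns, alongside the pixel data, the exact
core position, heading, midline, bend angle and event schedule of every larva
— so the tracking, tail, detection and classification stages can be validated
without any real video.

Geometry of the rendered larva (pixel units, 66 um/px default calibration):

* head: ellipse with semi-axes 8 x 5.5 px aligned with the heading;
* swim bladder: disk of radius 4 px, 9 px caudal to the head centre (rigid
  with the head, so the eroded core keeps a stable shape while the tail
  bends);
* tail: 40 px long, thickness tapering 2.0 -> 0.8 px, rendered as stamped
  disks along the midline; pixel intensity ramps from 60 at the base to 140
  at the tip so that raising the binarization threshold peels the tail from
  the tip inward (this is what makes intensity-based contact separation
  possible, as in real images where the thin tail is paler than the head).

Tail bending: the midline tangent turns by a total angle ``psi`` distributed
along the tail according to a per-maneuver weight profile — caudally
concentrated for slow forward swims, uniform (reaching the trunk) for turns
and escapes.  The scripted bend-angle amplitude is mapped to ``psi`` through
the small-angle gain of the profile so the realized tip angle tracks the
scripted waveform; ground truth always records the *realized* geometry.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.signal import windows
from skimage import draw

from ._geom import signed_angle, unit
from .calibration import CalibrationConfig

__all__ = [
    "ManeuverArchetype", "WellSpec", "LarvaSpec", "Layout", "ScriptedEvent",
    "TrueEvent", "LarvaTruth", "GroundTruth", "LayoutError", "ScheduleError",
    "ARCHETYPES", "render_video", "synth_bend_trace", "synth_movement",
    "single_well_layout", "ping_pong_script",
]

# body-plan constants (px at the default 66 um/px calibration)
HEAD_A = 8.0          # head ellipse semi-axis along the heading
HEAD_B = 5.5          # head ellipse semi-axis across the heading
BLADDER_R = 4.0
BLADDER_OFF = 9.0     # bladder centre, caudal to head centre
TAIL_LEN = 40.0
TAIL_R0, TAIL_R1 = 1.8, 0.8
HEAD_INT = 60.0
TAIL_INT0, TAIL_INT1 = 60.0, 140.0
BG_WELL = 230.0       # bright well interior
BG_OUTSIDE = 120.0    # darker surround between wells
N_TAIL_SAMPLES = 60
N_MIDLINE_POINTS = 10


class LayoutError(ValueError):
    """A larva does not fit inside its well."""


class ScheduleError(ValueError):
    """Scripted events overlap or fall outside the recording."""


# ----------------------------------------------------------------------
@dataclasses.dataclass(frozen=True)
class ManeuverArchetype:
    """One maneuver class: bend envelope, oscillation and translation."""

    label: str                 # 'S', 'T' or 'E'
    amp_deg: float             # peak tail-bending amplitude
    freq_hz: float             # left-right alternation frequency
    duration_ms: float
    speed_mm_s: float          # peak translation speed
    heading_change_deg: float  # net heading change over the maneuver
    bend_weight: str = "uniform"   # 'caudal' or 'uniform' curvature profile
    taper: float = 0.2         # Tukey-envelope taper fraction


# Defaults consistent with group recordings of 5-7 dpf larvae: slow swims
# around 20-25 Hz with caudally confined bending, routine turns with a large
# slow rostral bend, escapes with large fast alternation.
ARCHETYPES = {
    "S": ManeuverArchetype("S", amp_deg=20.0, freq_hz=25.0, duration_ms=200.0,
                           speed_mm_s=10.0, heading_change_deg=5.0,
                           bend_weight="caudal"),
    "T": ManeuverArchetype("T", amp_deg=55.0, freq_hz=12.0, duration_ms=160.0,
                           speed_mm_s=8.0, heading_change_deg=60.0,
                           bend_weight="uniform"),
    "E": ManeuverArchetype("E", amp_deg=65.0, freq_hz=35.0, duration_ms=250.0,
                           speed_mm_s=28.0, heading_change_deg=110.0,
                           bend_weight="uniform"),
}


@dataclasses.dataclass(frozen=True)
class WellSpec:
    center: tuple[float, float]   # (x, y)
    radius: float
    index: int


@dataclasses.dataclass(frozen=True)
class LarvaSpec:
    larva_id: int
    well: int
    position: tuple[float, float]   # initial head centre (x, y)
    heading: float                  # initial heading, rad


@dataclasses.dataclass(frozen=True)
class Layout:
    shape: tuple[int, int]          # (height, width)
    wells: list[WellSpec]
    larvae: list[LarvaSpec]


@dataclasses.dataclass(frozen=True)
class ScriptedEvent:
    start_frame: int
    archetype: ManeuverArchetype


@dataclasses.dataclass(frozen=True)
class TrueEvent:
    start: int      # frame, inclusive
    end: int        # frame, inclusive
    label: str


@dataclasses.dataclass
class LarvaTruth:
    larva_id: int
    well: int
    core: np.ndarray        # (T, 2) eroded-core centroid, px
    heading: np.ndarray     # (T,) rad
    bend_deg: np.ndarray    # (T,) realized tail-bending angle
    midline: np.ndarray     # (T, 10, 2) head centre -> tail tip, px
    events: list[TrueEvent]

    @property
    def tip(self) -> np.ndarray:
        return self.midline[:, -1, :]


@dataclasses.dataclass
class GroundTruth:
    n_frames: int
    wells: list[WellSpec]
    larvae: list[LarvaTruth]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "n_frames": self.n_frames,
            "wells": [{"center": list(w.center), "radius": w.radius,
                       "index": w.index} for w in self.wells],
            "larvae": [{
                "larva_id": lv.larva_id, "well": lv.well,
                "core": lv.core.tolist(), "heading": lv.heading.tolist(),
                "bend_deg": lv.bend_deg.tolist(),
                "midline": lv.midline.tolist(),
                "events": [dataclasses.asdict(e) for e in lv.events],
            } for lv in self.larvae],
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        wells = [WellSpec(tuple(w["center"]), w["radius"], w["index"])
                 for w in obj["wells"]]
        larvae = [LarvaTruth(
            larva_id=lv["larva_id"], well=lv["well"],
            core=np.asarray(lv["core"]), heading=np.asarray(lv["heading"]),
            bend_deg=np.asarray(lv["bend_deg"]),
            midline=np.asarray(lv["midline"]),
            events=[TrueEvent(**e) for e in lv["events"]],
        ) for lv in obj["larvae"]]
        return cls(obj["n_frames"], wells, larvae)


# ----------------------------------------------------------------------
# tail geometry

def _bend_profile(kind: str, n: int) -> tuple[np.ndarray, float]:
    """Cumulative turn distribution C(s) on [0, 1] and its small-angle gain.

    The realized tip angle for a small total turn psi is approximately
    ``psi * gain`` with ``gain = mean(C)``; caudal confinement gives a
    smaller gain than a uniform profile.
    """
    s = np.linspace(0.0, 1.0, n)
    if kind == "caudal":
        w = s ** 2
    elif kind == "uniform":
        w = np.ones_like(s)
    else:
        raise ValueError(f"unknown bend_weight {kind!r}")
    c = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2)])
    c /= c[-1]
    gain = float(np.trapezoid(c, s))
    return c, gain


def tail_curve(p_head: np.ndarray, heading: float, psi: float,
               bend_weight: str, n: int = N_TAIL_SAMPLES) -> np.ndarray:
    """Sampled tail midline from the bladder caudally, (n, 2) px."""
    c, _ = _bend_profile(bend_weight, n)
    phi = heading + np.pi + psi * c          # tangent angle along the tail
    ds = TAIL_LEN / (n - 1)
    # midpoint tangent for each segment keeps arc length exact
    phi_mid = (phi[:-1] + phi[1:]) / 2
    steps = ds * np.column_stack([np.cos(phi_mid), np.sin(phi_mid)])
    base = p_head - BLADDER_OFF * unit(heading)
    return np.vstack([base, base + np.cumsum(steps, axis=0)])


def _psi_for_amp(amp_deg: float, bend_weight: str) -> float:
    _, gain = _bend_profile(bend_weight, N_TAIL_SAMPLES)
    return np.deg2rad(amp_deg) / gain


# ----------------------------------------------------------------------
# rendering

def _stamp_disk(img: np.ndarray, center_xy: np.ndarray, radius: float,
                value: float) -> None:
    rr, cc = draw.disk((center_xy[1], center_xy[0]), max(radius, 0.8),
                       shape=img.shape)
    img[rr, cc] = np.minimum(img[rr, cc], value)


def _render_larva(img: np.ndarray, p_head: np.ndarray, heading: float,
                  tail: np.ndarray) -> None:
    """Draw one larva (head ellipse + bladder + tapering tail) in place."""
    rr, cc = draw.ellipse(p_head[1], p_head[0], HEAD_B, HEAD_A,
                          shape=img.shape, rotation=-heading)
    img[rr, cc] = np.minimum(img[rr, cc], HEAD_INT)
    _stamp_disk(img, p_head - BLADDER_OFF * unit(heading), BLADDER_R, HEAD_INT)
    n = len(tail)
    s = np.linspace(0.0, 1.0, n)
    radii = TAIL_R0 + (TAIL_R1 - TAIL_R0) * s
    vals = TAIL_INT0 + (TAIL_INT1 - TAIL_INT0) * s
    for p, r, v in zip(tail, radii, vals):
        _stamp_disk(img, p, r, v)


def _erosion_structure() -> np.ndarray:
    return np.ones((3, 3), dtype=bool)


def _clean_core_and_pivot(p_head: np.ndarray, heading: float,
                          tail: np.ndarray, cfg: CalibrationConfig,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth eroded-core centroid and bend pivot for one pose.

    Computed from a noise-free rendering of the larva alone, binarized and
    eroded exactly as the tracker does, so the truth matches what a perfect
    tracker would measure on clean pixels.
    """
    pts = np.vstack([tail, [p_head]])
    lo = np.floor(pts.min(axis=0)).astype(int) - 12
    hi = np.ceil(pts.max(axis=0)).astype(int) + 12
    size = hi - lo + 1
    patch = np.full((size[1], size[0]), BG_WELL)
    _render_larva(patch, p_head - lo, heading, tail - lo)
    binary = (BG_WELL - patch) > cfg.binarize_threshold
    eroded = ndimage.binary_erosion(binary, _erosion_structure(),
                                    iterations=cfg.erosion_iterations)
    labels, n = ndimage.label(eroded)
    if n == 0:
        core = p_head.copy()
        area = np.pi * HEAD_A * HEAD_B
    else:
        counts = np.bincount(labels.ravel())[1:]
        best = int(np.argmax(counts)) + 1
        ys, xs = np.nonzero(labels == best)
        core = np.array([xs.mean(), ys.mean()]) + lo
        area = counts[best - 1]
    head_radius = np.sqrt(area / np.pi)
    pivot = core - head_radius * unit(heading)
    return core, pivot


def _gt_midline(pivot: np.ndarray, tail: np.ndarray) -> np.ndarray:
    from ._geom import resample_polyline
    return resample_polyline(np.vstack([[pivot], tail]), N_MIDLINE_POINTS)


# ----------------------------------------------------------------------
# pose simulation

def _event_profiles(arch: ManeuverArchetype, fs: float,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame (bend_deg, speed_px, dheading_rad) over one maneuver."""
    n = max(int(round(arch.duration_ms * fs / 1000.0)), 4)
    t = np.arange(n) / fs
    env = windows.tukey(n, alpha=2 * arch.taper)
    bend = arch.amp_deg * env * np.sin(2 * np.pi * arch.freq_hz * t)
    speed = arch.speed_mm_s * env          # mm/s, converted by the caller
    w = env / env.sum() if env.sum() > 0 else np.full(n, 1.0 / n)
    dheading = np.deg2rad(arch.heading_change_deg) * w
    return bend, speed, dheading


def render_video(cfg: CalibrationConfig, layout: Layout,
                 script: dict[int, list[ScriptedEvent]], n_frames: int,
                 seed: int, noise_sd: float = 2.0,
                 ) -> tuple[np.ndarray, GroundTruth]:
    """Render a recording and its exact ground truth.

    Parameters
    ----------
    script
        Maps ``larva_id`` to a list of :class:`ScriptedEvent`; events of one
        larva must not overlap.  Outside events the larva rests (bend 0, no
        translation).
    noise_sd
        Gaussian pixel noise (0-255 scale) added after rendering.

    Returns
    -------
    frames : (n_frames, H, W) uint8
    truth : GroundTruth
    """
    rng = np.random.default_rng(seed)
    h, w = layout.shape
    wells = {wl.index: wl for wl in layout.wells}

    for lv in layout.larvae:
        wl = wells[lv.well]
        d = np.hypot(lv.position[0] - wl.center[0], lv.position[1] - wl.center[1])
        if d > wl.radius - HEAD_A:
            raise LayoutError(
                f"larva {lv.larva_id} placed outside well {lv.well} "
                f"(distance {d:.1f} px, radius {wl.radius:.1f} px)")

    # validate the schedule and expand per-frame pose controls
    controls = {}
    for lv in layout.larvae:
        events = sorted(script.get(lv.larva_id, []), key=lambda e: e.start_frame)
        bend = np.zeros(n_frames)
        speed = np.zeros(n_frames)
        dheading = np.zeros(n_frames)
        weight = np.empty(n_frames, dtype=object)
        weight[:] = "caudal"
        true_events = []
        prev_end = -1
        for ev in events:
            b, s, dh = _event_profiles(ev.archetype, cfg.frame_rate_hz)
            start, end = ev.start_frame, ev.start_frame + len(b) - 1
            if start <= prev_end:
                raise ScheduleError(
                    f"larva {lv.larva_id}: event at frame {start} overlaps "
                    f"the previous one (ends {prev_end})")
            if start < 0 or end >= n_frames:
                raise ScheduleError(
                    f"larva {lv.larva_id}: event [{start}, {end}] outside "
                    f"recording of {n_frames} frames")
            bend[start:end + 1] = b
            speed[start:end + 1] = s
            dheading[start:end + 1] = dh
            weight[start:end + 1] = ev.archetype.bend_weight
            true_events.append(TrueEvent(start, end, ev.archetype.label))
            prev_end = end
        controls[lv.larva_id] = (bend, speed, dheading, weight, true_events)

    # static background: dark surround, bright well disks
    base = np.full((h, w), BG_OUTSIDE)
    for wl in layout.wells:
        rr, cc = draw.disk((wl.center[1], wl.center[0]), wl.radius, shape=(h, w))
        base[rr, cc] = BG_WELL

    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    truths = []
    poses = {lv.larva_id: [np.array(lv.position, dtype=float), lv.heading]
             for lv in layout.larvae}
    per_larva = {lv.larva_id: {
        "core": np.zeros((n_frames, 2)), "heading": np.zeros(n_frames),
        "bend": np.zeros(n_frames), "midline": np.zeros((n_frames, N_MIDLINE_POINTS, 2)),
    } for lv in layout.larvae}

    px_per_frame = 1.0 / (cfg.pixel_size_mm * cfg.frame_rate_hz)
    for f in range(n_frames):
        img = base.copy()
        for lv in layout.larvae:
            bend, speed, dheading, weight, _ = controls[lv.larva_id]
            pos, heading = poses[lv.larva_id]
            heading = (heading + dheading[f]) % (2 * np.pi)
            pos = pos + speed[f] * px_per_frame * unit(heading)
            poses[lv.larva_id] = [pos, heading]

            wl = wells[lv.well]
            if np.hypot(pos[0] - wl.center[0], pos[1] - wl.center[1]) > wl.radius - HEAD_A:
                raise LayoutError(
                    f"larva {lv.larva_id} left well {lv.well} at frame {f}; "
                    "adjust the script")

            psi = _psi_for_amp(bend[f], weight[f])
            tail = tail_curve(pos, heading, psi, weight[f])
            _render_larva(img, pos, heading, tail)

            core, pivot = _clean_core_and_pivot(pos, heading, tail, cfg)
            tailward = -unit(heading)
            rec = per_larva[lv.larva_id]
            rec["core"][f] = core
            rec["heading"][f] = heading
            rec["bend"][f] = np.rad2deg(signed_angle(tailward, tail[-1] - pivot))
            rec["midline"][f] = _gt_midline(pivot, tail)

        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames[f] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    for lv in layout.larvae:
        rec = per_larva[lv.larva_id]
        truths.append(LarvaTruth(
            larva_id=lv.larva_id, well=lv.well, core=rec["core"],
            heading=rec["heading"], bend_deg=rec["bend"],
            midline=rec["midline"], events=controls[lv.larva_id][4]))
    return frames, GroundTruth(n_frames, layout.wells, truths)


# ----------------------------------------------------------------------
# 1-D trace fixtures (no imaging)

def synth_bend_trace(schedule: list[tuple[ManeuverArchetype, float]],
                     duration_ms: float, noise_sd: float, seed: int,
                     frame_rate_hz: float = 337.0,
                     ) -> tuple[np.ndarray, list[TrueEvent]]:
    """Bend-angle time series (deg) with exact event boundaries.

    ``schedule`` lists (archetype, start time in ms); events must not
    overlap.  Baseline is 0 deg; each event contributes an enveloped
    oscillation; Gaussian noise is added on top.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms * frame_rate_hz / 1000.0))
    trace = np.zeros(n)
    events: list[TrueEvent] = []
    prev_end = -1
    for arch, start_ms in sorted(schedule, key=lambda x: x[1]):
        b, _, _ = _event_profiles(arch, frame_rate_hz)
        start = int(round(start_ms * frame_rate_hz / 1000.0))
        end = start + len(b) - 1
        if start <= prev_end:
            raise ScheduleError(f"event at {start_ms} ms overlaps the previous one")
        if start < 0 or end >= n:
            raise ScheduleError(f"event at {start_ms} ms falls outside the trace")
        trace[start:end + 1] += b
        events.append(TrueEvent(start, end, arch.label))
        prev_end = end
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, n)
    return trace, events


def synth_movement(arch: ManeuverArchetype, noise_sd: float, seed: int,
                   cfg: CalibrationConfig, pad_frames: int = 20,
                   jitter: float = 0.15,
                   ) -> tuple[np.ndarray, np.ndarray, TrueEvent]:
    """One maneuver as (bend trace deg, core track px, event).

    Used to exercise feature extraction and classification without imaging.
    ``jitter`` scales multiplicative variation of amplitude, frequency and
    speed between draws so classes form clouds rather than single points.
    """
    rng = np.random.default_rng(seed)
    fs = cfg.frame_rate_hz
    varied = dataclasses.replace(
        arch,
        amp_deg=arch.amp_deg * float(rng.lognormal(0, jitter)),
        freq_hz=arch.freq_hz * float(rng.lognormal(0, jitter / 2)),
        speed_mm_s=arch.speed_mm_s * float(rng.lognormal(0, jitter)),
        duration_ms=arch.duration_ms * float(rng.lognormal(0, jitter / 2)),
    )
    bend, speed, dheading = _event_profiles(varied, fs)
    n = len(bend) + 2 * pad_frames
    trace = np.zeros(n)
    trace[pad_frames:pad_frames + len(bend)] = bend
    if noise_sd > 0:
        trace += rng.normal(0.0, noise_sd, n)
    heading = np.cumsum(np.concatenate(
        [np.zeros(pad_frames), dheading, np.zeros(pad_frames)]))
    spd = np.concatenate([np.zeros(pad_frames), speed, np.zeros(pad_frames)])
    step = spd / (cfg.pixel_size_mm * fs)
    track = np.cumsum(step[:, None] * np.column_stack(
        [np.cos(heading), np.sin(heading)]), axis=0) + 100.0
    event = TrueEvent(pad_frames, pad_frames + len(bend) - 1, arch.label)
    return trace, track, event


# ----------------------------------------------------------------------
# canned layouts and scripts

def single_well_layout(n_larvae: int, radius: float = 160.0,
                       margin: int = 20, orbit_radius: float = 70.0,
                       ) -> Layout:
    """One circular well with larvae on a radial star, heading outward."""
    c = radius + margin
    size = int(2 * c)
    well = WellSpec((c, c), radius, 0)
    larvae = []
    for k in range(n_larvae):
        ang = 2 * np.pi * k / max(n_larvae, 1)
        pos = (c + orbit_radius * np.cos(ang), c + orbit_radius * np.sin(ang))
        larvae.append(LarvaSpec(larva_id=k, well=0, position=pos, heading=ang))
    return Layout((size, size), [well], larvae)


def crossing_layout(angle_deg: float, offset: float = 0.0,
                    radius: float = 160.0, approach: float = 80.0) -> Layout:
    """Two larvae aimed to cross paths at the well centre.

    ``angle_deg`` is the angle between the two swimming directions (180 =
    head-on); ``offset`` displaces the second larva's track laterally so
    the pass is glancing rather than exactly centred.
    """
    c = radius + 20.0
    well = WellSpec((c, c), radius, 0)
    a1, a2 = 0.0, np.deg2rad(angle_deg)
    d2 = unit(a2)
    perp2 = np.array([-d2[1], d2[0]])
    p1 = np.array([c, c]) - approach * unit(a1)
    p2 = np.array([c, c]) - approach * d2 + offset * perp2
    return Layout((int(2 * c), int(2 * c)), [well], [
        LarvaSpec(0, 0, tuple(p1), a1),
        LarvaSpec(1, 0, tuple(p2), a2)])


def crossing_script(cfg: CalibrationConfig, duration_ms: float = 650.0,
                    start_frame: int = 5) -> dict[int, list[ScriptedEvent]]:
    """Both larvae perform one long straight forward swim through the
    crossing point (low bend amplitude, no net heading change)."""
    swim = dataclasses.replace(ARCHETYPES["S"], duration_ms=duration_ms,
                               heading_change_deg=0.0, amp_deg=12.0,
                               speed_mm_s=12.0)
    return {0: [ScriptedEvent(start_frame, swim)],
            1: [ScriptedEvent(start_frame, swim)]}


def multi_well_layout(n_wells: int, n_larvae: int, radius: float = 160.0,
                      margin: int = 20, per_row: int = 4) -> Layout:
    """Grid of identical circular wells, larvae on a radial star in each."""
    if n_wells == 1:
        return single_well_layout(n_larvae, radius, margin)
    pitch = int(2 * (radius + margin))
    ncol = min(per_row, n_wells)
    nrow = int(np.ceil(n_wells / ncol))
    wells, larvae = [], []
    for k in range(n_wells):
        r, c = divmod(k, ncol)
        cx = c * pitch + radius + margin
        cy = r * pitch + radius + margin
        wells.append(WellSpec((cx, cy), radius, k))
        for j in range(n_larvae):
            ang = 2 * np.pi * j / max(n_larvae, 1)
            pos = (cx + 70.0 * np.cos(ang), cy + 70.0 * np.sin(ang))
            larvae.append(LarvaSpec(larva_id=k * n_larvae + j, well=k,
                                    position=pos, heading=ang))
    return Layout((nrow * pitch, ncol * pitch), wells, larvae)


def ping_pong_script(layout: Layout, n_frames: int, cfg: CalibrationConfig,
                     rest_ms: float = 120.0, stagger_frames: int = 9,
                     ) -> dict[int, list[ScriptedEvent]]:
    """Out-and-back schedule: forward swims alternating with 180-deg turns.

    Each larva shuttles along its own radial corridor, which keeps the
    larvae apart (no collisions) while every body pixel is vacated at some
    point — a requirement for max-projection background estimation.
    """
    swim = ARCHETYPES["S"]
    turn = dataclasses.replace(ARCHETYPES["T"], heading_change_deg=180.0,
                               speed_mm_s=4.0, duration_ms=160.0)
    rest = int(round(rest_ms * cfg.frame_rate_hz / 1000.0))
    script: dict[int, list[ScriptedEvent]] = {}
    for i, lv in enumerate(layout.larvae):
        events = []
        f = rest + (i * stagger_frames) % rest
        which = 0
        while True:
            arch = swim if which % 2 == 0 else turn
            n_ev = max(int(round(arch.duration_ms * cfg.frame_rate_hz / 1000.0)), 4)
            if f + n_ev >= n_frames - 1:
                break
            events.append(ScriptedEvent(f, arch))
            f += n_ev + rest
            which += 1
        script[lv.larva_id] = events
    return script
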