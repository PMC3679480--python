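import numpy as np
import pytest
from skimage import draw

from larvatrack import synth, tracking
from larvatrack.calibration import CalibrationConfig
from larvatrack.tracking import (WellDetectionError, assign_identities,
                                 compute_heading, detect_wells,
                                 estimate_background, segment_cores)


def _circle_image(centers, radius, shape):
    img = np.full(shape, 120, dtype=np.uint8)
    for cx, cy in centers:
        rr, cc = draw.disk((cy, cx), radius, shape=shape)
        img[rr, cc] = 230
    return img


class TestDetectWells:
    def test_eight_drawn_circles_recovered(self):
        centers = [(200 + 420 * c, 200 + 420 * r) for r in range(2)
                   for c in range(4)]
        img = _circle_image(centers, 160, (840, 1700))
        wells = detect_wells(img, 8, radius_range=np.arange(150, 172, 2))
        assert len(wells) == 8
        for w, (cx, cy) in zip(wells, centers):
            assert np.hypot(w.center[0] - cx, w.center[1] - cy) < 3.0

    def test_blank_image_raises(self):
        img = np.full((300, 300), 120, dtype=np.uint8)
        with pytest.raises(WellDetectionError, match="expected 8"):
            detect_wells(img, 8, radius_range=np.arange(40, 80, 4))

    def test_single_circle(self):
        img = _circle_image([(150, 150)], 100, (300, 300))
        wells = detect_wells(img, 1, radius_range=np.arange(90, 112, 2))
        assert len(wells) == 1
        assert np.hypot(wells[0].center[0] - 150, wells[0].center[1] - 150) < 3.0


class TestBackground:
    def test_identical_frames(self):
        f = np.random.default_rng(0).integers(0, 255, (5, 20, 20))
        bg = estimate_background(np.stack([f[0]] * 4))
        assert np.array_equal(bg, f[0])

    def test_moving_dark_object_removed_exactly(self):
        true_bg = np.full((30, 30), 200, dtype=np.uint8)
        frames = []
        for x in range(0, 30, 5):   # dark 3x3 blob visits disjoint spots
            f = true_bg.copy()
            f[10:13, x:x + 3] = 40
            frames.append(f)
        assert np.array_equal(estimate_background(np.stack(frames)), true_bg)

    def test_two_frame_pixelwise_max(self):
        a = np.full((4, 4), 10, dtype=np.uint8)
        b = np.full((4, 4), 200, dtype=np.uint8)
        assert estimate_background(np.stack([a, b]))[0, 0] == 200

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            estimate_background(np.zeros((1, 4, 4)))


class TestSegmentCores:
    def test_frame_equal_background_gives_no_candidates(self, cfg):
        bg = np.full((50, 50), 200.0)
        seg = segment_cores(bg, bg, cfg)
        assert seg.candidates == []

    def test_rendered_larva_found_within_one_pixel(self, cfg, single_larva_frame):
        _, _, gt, seg = single_larva_frame
        assert len(seg.candidates) == 1
        c = seg.candidates[0]
        assert cfg.core_area_min_px2 <= c.area <= cfg.core_area_max_px2
        assert np.hypot(*(c.centroid - gt.larvae[0].core[0])) < 1.0

    def test_double_erosion_of_5x5_square_leaves_one_pixel(self, cfg):
        frame = np.full((20, 20), 200.0)
        frame[8:13, 8:13] = 50.0
        seg = segment_cores(frame, np.full((20, 20), 200.0), cfg)
        assert seg.eroded.sum() == 1
        assert seg.eroded[10, 10]

    def test_threshold_monotonicity(self, single_larva_frame):
        _, frames, _, _ = single_larva_frame
        bg = np.full(frames[0].shape, 230.0)
        lo = segment_cores(frames[0], bg, CalibrationConfig(binarize_threshold=25))
        hi = segment_cores(frames[0], bg, CalibrationConfig(binarize_threshold=60))
        assert not (hi.binary & ~lo.binary).any()   # raising never grows


class TestComputeHeading:
    def test_axis_aligned_rectangle(self):
        ys, xs = np.nonzero(np.ones((3, 11)))
        h, ok = compute_heading((ys, xs))
        assert ok
        assert min(abs(h), abs(h - np.pi), abs(h - 2 * np.pi)) < 1e-6

    def test_rotated_rectangle(self):
        yy, xx = np.mgrid[0:60, 0:60]
        ang = np.deg2rad(30)
        u = (xx - 30) * np.cos(ang) + (yy - 30) * np.sin(ang)
        v = -(xx - 30) * np.sin(ang) + (yy - 30) * np.cos(ang)
        mask = (np.abs(u) <= 14) & (np.abs(v) <= 3)
        h, ok = compute_heading(np.nonzero(mask))
        assert ok
        dev = min(abs(h - ang), abs(h - ang - np.pi), abs(h - ang + np.pi),
                  abs(h - ang - 2 * np.pi))
        assert dev < np.deg2rad(1.0)

    def test_rendered_larva_head_forward(self, cfg):
        well = synth.WellSpec((100.0, 100.0), 90.0, 0)
        lv = synth.LarvaSpec(0, 0, (100.0, 80.0), np.pi / 2)   # facing +y
        layout = synth.Layout((200, 200), [well], [lv])
        frames, _ = synth.render_video(cfg, layout, {}, 2, seed=0, noise_sd=0.0)
        roi = tracking.WellROI(well.center, well.radius, 0).mask((200, 200))
        seg = segment_cores(frames[0], np.full((200, 200), 230.0), cfg, roi)
        h, ok = compute_heading(seg.candidates[0].pixels)
        assert ok
        assert abs(h - np.pi / 2) < 0.1

    def test_degenerate_component_returns_previous(self):
        rr, cc = draw.disk((10, 10), 5)
        h, ok = compute_heading((rr, cc), prev_heading=1.234)
        assert not ok
        assert h == 1.234


class TestAssignIdentities:
    def test_constant_velocity_prediction(self):
        cands = [tracking.CoreCandidate(np.array([14.0, 10.0]), 30,
                                        (np.array([10]), np.array([14]))),
                 tracking.CoreCandidate(np.array([50.0, 50.0]), 30,
                                        (np.array([50]), np.array([50])))]
        prev = {0: [np.array([10.0, 10.0]), np.array([12.0, 10.0])]}
        states, col = assign_identities(cands, prev, frame=2)
        assert np.allclose(states[0].position, [14.0, 10.0])
        assert col == []

    def test_no_candidates_carries_positions_invalid(self):
        prev = {0: [np.array([5.0, 5.0])], 1: [np.array([9.0, 9.0])]}
        states, _ = assign_identities([], prev, frame=1)
        assert not states[0].valid and not states[1].valid
        assert np.allclose(states[0].position, [5.0, 5.0])

    def test_shared_nearest_candidate_flags_collision(self):
        cands = [tracking.CoreCandidate(np.array([10.0, 10.0]), 30,
                                        (np.array([10]), np.array([10])))]
        prev = {0: [np.array([9.0, 10.0])], 1: [np.array([11.0, 10.0])]}
        states, col = assign_identities(cands, prev, frame=1)
        assert col == [(0, 1)]
        assert states[0].collision_with == 1
        assert states[1].collision_with == 0
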