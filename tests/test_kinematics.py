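import numpy as np
import pytest

from larvatrack import synth
from larvatrack._geom import rotate
from larvatrack.bouts import MovementEvent
from larvatrack.kinematics import (compute_curvature, compute_global_params,
                                   midline_curvature)


def _event(n):
    return MovementEvent(0, 0, 0, n - 1)


class TestGlobalParams:
    def test_pure_sine_oscillations_and_tbf(self, cfg):
        fs = cfg.frame_rate_hz
        n = int(round(0.2 * fs))
        trace = 20 * np.sin(2 * np.pi * 25 * np.arange(n) / fs)
        gp = compute_global_params(_event(n), trace, np.zeros((n, 2)),
                                   np.zeros(n), cfg)
        assert gp.oscillations == pytest.approx(5.0, abs=0.5)
        assert gp.tbf_hz == pytest.approx(25.0, rel=0.05)
        assert gp.distance_mm == 0.0
        assert gp.speed_mm_s == 0.0

    def test_straight_travel_distance_and_speed(self, cfg):
        fs = cfg.frame_rate_hz
        n = int(round(0.15 * fs)) + 1
        track = np.column_stack([np.linspace(0, 3.0 / cfg.pixel_size_mm, n),
                                 np.zeros(n)])
        gp = compute_global_params(_event(n), np.zeros(n), track,
                                   np.zeros(n), cfg)
        assert gp.distance_mm == pytest.approx(3.0, rel=1e-6)
        assert gp.speed_mm_s == pytest.approx(gp.distance_mm / (n / fs) * 1.0,
                                              rel=1e-6)
        assert gp.heading_range_deg == 0.0
        # speed x duration recovers distance exactly by construction
        assert gp.speed_mm_s * gp.duration_ms / 1000.0 == pytest.approx(
            gp.distance_mm, rel=1e-9)

    def test_monotone_heading_rotation_range(self, cfg):
        n = 60
        heading = np.deg2rad(np.linspace(10.0, 50.0, n))
        gp = compute_global_params(_event(n), np.zeros(n), np.zeros((n, 2)),
                                   heading, cfg)
        assert gp.heading_range_deg == pytest.approx(40.0, abs=1e-6)

    def test_heading_range_unaffected_by_wraparound(self, cfg):
        n = 60
        heading = np.mod(np.linspace(-0.3, 0.3, n), 2 * np.pi)   # crosses 0
        gp = compute_global_params(_event(n), np.zeros(n), np.zeros((n, 2)),
                                   heading, cfg)
        assert gp.heading_range_deg == pytest.approx(np.rad2deg(0.6), abs=1e-6)

    def test_degenerate_event_rejected(self, cfg):
        with pytest.raises(ValueError):
            compute_global_params(MovementEvent(0, 0, 5, 5), np.zeros(10),
                                  np.zeros((10, 2)), np.zeros(10), cfg)


class TestCurvature:
    def test_circular_arc(self, cfg):
        th = np.linspace(0.3, 1.5, 30)
        pts = np.column_stack([10 * np.cos(th), 10 * np.sin(th)])
        c = midline_curvature(pts, cfg)
        assert np.allclose(c, 1.0 / (10 * cfg.pixel_size_mm), rtol=0.02)

    def test_straight_midline_zero(self, cfg):
        pts = np.column_stack([np.linspace(0, 40, 10), np.zeros(10)])
        assert midline_curvature(pts, cfg).max() < 1e-6

    def test_scaling_covariance(self, cfg):
        th = np.linspace(0.3, 1.5, 30)
        pts = np.column_stack([8 * np.cos(th), 8 * np.sin(th)])
        c1 = midline_curvature(pts, cfg)
        c2 = midline_curvature(2 * pts, cfg)
        assert np.allclose(c2, c1 / 2, rtol=1e-6)

    def test_rigid_motion_invariance(self, cfg):
        th = np.linspace(0.3, 1.5, 30)
        pts = np.column_stack([12 * np.cos(th), 12 * np.sin(th)])
        base = midline_curvature(pts, cfg)
        moved = midline_curvature(rotate(pts, 1.1, origin=(4, -2)) + [7, 3], cfg)
        assert np.max(np.abs(moved - base) / base) < 1e-9

    def test_kymograph_caudal_confinement_by_maneuver(self, cfg):
        # slow-swim bending is caudally confined; turn/escape bending
        # reaches the rostral tail
        def kymo(weight, amp):
            mids = []
            for phase in np.linspace(0, 2 * np.pi, 12, endpoint=False):
                psi = synth._psi_for_amp(amp * np.sin(phase), weight)
                mids.append(synth.tail_curve(np.array([100.0, 100.0]), 0.0,
                                             psi, weight))
            return compute_curvature(mids, cfg)

        for weight, amp, caudal_expected in [("caudal", 20.0, True),
                                             ("uniform", 55.0, False)]:
            k = kymo(weight, amp)
            v = k.values[k.valid]
            thr = np.quantile(v[v > 0], 0.75)
            high_pos = np.broadcast_to(k.positions, v.shape)[v >= thr]
            caudal_frac = float(np.mean(high_pos > 0.5))
            if caudal_expected:
                assert caudal_frac > 0.9
            else:
                assert caudal_frac < 0.75

    def test_degenerate_midline_row_flagged(self, cfg):
        good = np.column_stack([np.linspace(0, 30, 10), np.zeros(10)])
        bad = np.zeros((3, 2))
        k = compute_curvature([good, bad], cfg)
        assert k.valid[0] and not k.valid[1]
        assert np.all(k.values[1] == 0.0)
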