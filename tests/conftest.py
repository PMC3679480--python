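import numpy as np
import pytest

from larvatrack import synth, tracking
from larvatrack.calibration import CalibrationConfig


@pytest.fixture(scope="session")
def cfg() -> CalibrationConfig:
    return CalibrationConfig()


@pytest.fixture(scope="session")
def small_video(cfg):
    """120-frame, 2-larva rendering with ground truth (shared, read-only)."""
    layout = synth.single_well_layout(2)
    script = synth.ping_pong_script(layout, 120, cfg)
    frames, gt = synth.render_video(cfg, layout, script, 120, seed=11)
    return layout, frames, gt


@pytest.fixture(scope="session")
def single_larva_frame(cfg):
    """One resting larva, heading +x, clean-ish scene plus segmentation."""
    layout = synth.single_well_layout(1)
    frames, gt = synth.render_video(cfg, layout, {}, 3, seed=5, noise_sd=0.5)
    well = tracking.WellROI(layout.wells[0].center, layout.wells[0].radius, 0)
    bg = np.full(frames[0].shape, float(synth.BG_WELL))
    seg = tracking.segment_cores(frames[0], bg, cfg, well.mask(frames[0].shape))
    return layout, frames, gt, seg
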