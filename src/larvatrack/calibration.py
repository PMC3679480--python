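"""Calibration and pipeline thresholds in physical units.

Every numeric threshold of the pipeline lives here, expressed in the unit it
is naturally stated in (mm, mm^2, ms, degrees, frames).  Conversion to pixels
and frames happens at the use site through :meth:`CalibrationConfig.to_pixels`
and the derived properties, so a recording at a different magnification or
frame rate only needs ``pixel_size_mm`` / ``frame_rate_hz`` changed.

Defaults correspond to a standard multi-well setup: 66 um pixels, 337 Hz
acquisition, 5-7 dpf larvae whose eroded core covers 0.0871-0.8712 mm^2 and
whose tail (head centre to tip) measures 1.32-3.96 mm.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import yaml

__all__ = ["CalibrationConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for malformed config files or invariant violations."""


@dataclasses.dataclass
class CalibrationConfig:
    # --- optics / acquisition ---
    pixel_size_mm: float = 0.066
    frame_rate_hz: float = 337.0
    # --- core segmentation ---
    core_area_min_mm2: float = 0.0871
    core_area_max_mm2: float = 0.8712
    binarize_threshold: float = 25.0      # absolute difference, 0-255 scale
    erosion_iterations: int = 2           # 3x3 square element, applied twice
    # --- tail validity ---
    tail_length_min_mm: float = 1.32
    tail_length_max_mm: float = 3.96
    candidate_ratio_soft: float = 0.20    # gates the max-y tail-tip candidate
    candidate_ratio_hard: float = 0.25    # excludes any tail-tip candidate
    median_filter_frames: int = 5         # bend-angle median filter window
    spline_smooth_px: float = 0.5         # midline smoothing residual per point
    # --- collision handling ---
    contact_area_mm2: float = 1.9
    contact_line_vs_threshold_mm: float = 1.32
    intensity_step: float = 5.0           # threshold increment, 0-255 scale
    intensity_cap: float = 250.0
    line_angles: int = 36
    # --- movement detection ---
    move_angle_delta_deg: float = 1.15
    move_window_frames: int = 10          # surrounding frames for running mean
    merge_gap_ms: float = 14.8
    min_displacement_mm: float = 0.099
    min_angle_range_deg: float = 2.86
    min_eroded_pixel_change: int = 3
    # --- kinematics ---
    oscillation_min_peak_deg: float = 5.0
    curvature_positions: int = 25
    # --- categorization ---
    svm_c: float = 1.0
    pca_components: int = 14
    # --- interactions ---
    min_pair_count: int = 20

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        positive = [
            "pixel_size_mm", "frame_rate_hz", "core_area_min_mm2",
            "core_area_max_mm2", "tail_length_min_mm", "tail_length_max_mm",
            "contact_area_mm2", "contact_line_vs_threshold_mm",
            "move_angle_delta_deg", "move_window_frames", "merge_gap_ms",
            "min_displacement_mm", "min_angle_range_deg",
            "candidate_ratio_soft", "candidate_ratio_hard",
            "binarize_threshold", "median_filter_frames",
            "oscillation_min_peak_deg", "svm_c", "intensity_step",
        ]
        for name in positive:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ConfigError(f"{name} must be a finite positive number, got {v!r}")
        for lo, hi in [("core_area_min_mm2", "core_area_max_mm2"),
                       ("tail_length_min_mm", "tail_length_max_mm"),
                       ("candidate_ratio_soft", "candidate_ratio_hard")]:
            if not getattr(self, lo) < getattr(self, hi):
                raise ConfigError(f"{lo} must be < {hi} "
                                  f"({getattr(self, lo)} >= {getattr(self, hi)})")
        for name in ["erosion_iterations", "move_window_frames",
                     "median_filter_frames", "min_eroded_pixel_change",
                     "curvature_positions", "pca_components", "line_angles",
                     "min_pair_count"]:
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")

    # ------------------------------------------------------------------
    # unit bridges
    def to_pixels(self, value_mm: float) -> float:
        """Length in mm -> length in pixels (exact floating division)."""
        return value_mm / self.pixel_size_mm

    def to_mm(self, value_px: float) -> float:
        return value_px * self.pixel_size_mm

    def area_to_px2(self, value_mm2: float) -> float:
        return value_mm2 / self.pixel_size_mm ** 2

    def ms_to_frames(self, value_ms: float) -> float:
        return value_ms * self.frame_rate_hz / 1000.0

    def frames_to_ms(self, n_frames: float) -> float:
        return n_frames * 1000.0 / self.frame_rate_hz

    # derived pixel/frame thresholds, pure functions of the physical values
    @property
    def core_area_min_px2(self) -> float:
        return self.area_to_px2(self.core_area_min_mm2)

    @property
    def core_area_max_px2(self) -> float:
        return self.area_to_px2(self.core_area_max_mm2)

    @property
    def tail_length_min_px(self) -> float:
        return self.to_pixels(self.tail_length_min_mm)

    @property
    def tail_length_max_px(self) -> float:
        return self.to_pixels(self.tail_length_max_mm)

    @property
    def contact_area_px2(self) -> float:
        return self.area_to_px2(self.contact_area_mm2)

    @property
    def contact_line_vs_threshold_px(self) -> float:
        return self.to_pixels(self.contact_line_vs_threshold_mm)

    @property
    def min_displacement_px(self) -> float:
        return self.to_pixels(self.min_displacement_mm)

    @property
    def merge_gap_frames(self) -> float:
        return self.ms_to_frames(self.merge_gap_ms)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_NAMES = {f.name for f in dataclasses.fields(CalibrationConfig)}
_INT_FIELDS = {f.name for f in dataclasses.fields(CalibrationConfig) if f.type == "int"}


def load_config(path: str | Path | None = None) -> CalibrationConfig:
    """Load a flat ``key: value`` YAML config, or defaults if *path* is None.

    Unknown keys are rejected so a typo cannot silently fall back to a
    default; invariants are re-checked after overriding.
    """
    if path is None:
        return CalibrationConfig()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse config {path}{line}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a flat key: value mapping")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in _INT_FIELDS & set(data):
        v = data[key]
        if isinstance(v, float) and v.is_integer():
            data[key] = int(v)
    return CalibrationConfig(**data)
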