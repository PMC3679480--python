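"""Maneuver categorization: slow forward swim (S), routine turn (T), escape (E).

Each movement is summarized by four dynamic series aligned to the peak of
its first tail bend — bend-angle amplitude (0-178 ms, 12 ms bins),
instantaneous left-right alternation frequency (0-104 ms, 7 ms bins),
cumulative bend angle (running mean of |angle|, 0-178 ms, 12 ms bins) and
speed (0-240 ms, 24 ms bins) — giving 53 raw components, plus the total
movement duration.  The 53 components are z-scored, reduced to 14 principal
components, the (z-scored) duration is appended, and two successive linear
SVMs decide S vs. {T, E}, then T vs. E.

Amplitude-type features use |angle|, so categorization is invariant to
mirroring the larva left-right.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import interpolate, signal
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .bouts import MovementEvent
from .calibration import CalibrationConfig

__all__ = ["FeatureVector", "ClassifierModel", "FeatureExtractionError",
           "extract_features", "fit_model", "classify", "FEATURE_BINS"]

# (window_ms, bin_ms, n_bins) per dynamic parameter; 15+14+14+10 = 53
FEATURE_BINS = {
    "amplitude": (178.0, 12.0, 15),
    "frequency": (104.0, 7.0, 14),
    "cumulative": (178.0, 12.0, 14),
    "speed": (240.0, 24.0, 10),
}
RAW_DIM = sum(n for _, _, n in FEATURE_BINS.values())
CLASSES = ("S", "T", "E")


class FeatureExtractionError(RuntimeError):
    pass


@dataclasses.dataclass
class FeatureVector:
    raw: np.ndarray            # (53,)
    duration_ms: float
    padded: bool               # True when the event was shorter than a window


def _bin_centers(name: str) -> np.ndarray:
    _, width, n = FEATURE_BINS[name]
    return (np.arange(n) + 0.5) * width


def _spline_sample(t_ms: np.ndarray, values: np.ndarray,
                   query_ms: np.ndarray) -> np.ndarray:
    """Spline interpolation with last/first-value extrapolation."""
    if len(t_ms) == 1:
        return np.full(len(query_ms), values[0])
    kind = "cubic" if len(t_ms) >= 4 else "linear"
    f = interpolate.interp1d(t_ms, values, kind=kind, bounds_error=False,
                             fill_value=(values[0], values[-1]))
    return f(np.clip(query_ms, t_ms[0], t_ms[-1]))


def extract_features(event: MovementEvent, trace: np.ndarray,
                     track: np.ndarray, cfg: CalibrationConfig,
                     peak_min_deg: float = 2.0) -> FeatureVector:
    """Dynamic feature vector for one movement.

    Time zero is the peak of the first tail bend (first extremum of the
    bend angle above ``peak_min_deg``); events shorter than a feature
    window are padded by last-value extrapolation and flagged.
    """
    fs = cfg.frame_rate_hz
    seg = np.asarray(trace, dtype=float)[event.start:event.end + 1]
    pos = np.asarray(track, dtype=float)[event.start:event.end + 1]
    absseg = np.abs(seg)
    peaks, _ = signal.find_peaks(absseg, height=peak_min_deg)
    if peaks.size == 0:
        raise FeatureExtractionError("no bend extremum found in the event")
    i0 = int(peaks[0])
    t_ms = (np.arange(len(seg)) - i0) * 1000.0 / fs
    after = t_ms >= 0

    amp = _spline_sample(t_ms[after], absseg[after], _bin_centers("amplitude"))

    # instantaneous frequency from successive signed extrema: one half
    # period between an extremum and the next, held piecewise-constant
    hi, _ = signal.find_peaks(seg, height=peak_min_deg)
    lo, _ = signal.find_peaks(-seg, height=peak_min_deg)
    ext = np.sort(np.concatenate([hi, lo]))
    ext = ext[ext >= i0]
    qf = _bin_centers("frequency")
    if ext.size >= 2:
        # refine extremum times to subframe precision with a parabola
        # through the three samples around each peak
        t_ref = ext.astype(float)
        for m, i in enumerate(ext):
            if 0 < i < len(seg) - 1:
                y0, y1, y2 = np.abs(seg[i - 1:i + 2])
                den = y0 - 2 * y1 + y2
                if den != 0:
                    t_ref[m] = i + 0.5 * (y0 - y2) / den
        t_ext = (t_ref - i0) * 1000.0 / fs
        half = np.diff(t_ext)
        freqs = 1000.0 / (2.0 * half)
        idx = np.clip(np.searchsorted(t_ext[1:], qf), 0, len(freqs) - 1)
        freq = freqs[idx]
    else:
        freq = np.zeros(len(qf))

    cum = np.cumsum(absseg[after]) / np.arange(1, after.sum() + 1)
    cumulative = _spline_sample(t_ms[after], cum, _bin_centers("cumulative"))

    step_mm = np.hypot(*np.diff(pos, axis=0).T) * cfg.pixel_size_mm
    speed_series = np.concatenate([[0.0], step_mm * fs])
    speed = _spline_sample(t_ms[after], speed_series[after], _bin_centers("speed"))

    raw = np.concatenate([amp, freq, cumulative, speed])
    assert raw.shape == (RAW_DIM,)
    duration_ms = event.n_frames * 1000.0 / fs
    padded = t_ms[-1] < max(w for w, _, _ in FEATURE_BINS.values())
    return FeatureVector(raw, duration_ms, padded)


# ----------------------------------------------------------------------
@dataclasses.dataclass
class _LinearStage:
    coef: np.ndarray
    intercept: float
    positive_label: str
    negative_label: str

    def decide(self, x: np.ndarray) -> str:
        score = float(x @ self.coef + self.intercept)
        return self.positive_label if score > 0 else self.negative_label


@dataclasses.dataclass
class ClassifierModel:
    """PCA basis + two linear separators, portable as JSON."""

    feat_mean: np.ndarray
    feat_scale: np.ndarray
    pca_mean: np.ndarray
    pca_components: np.ndarray      # (14, 53)
    dur_mean: float
    dur_scale: float
    stage1: _LinearStage            # S vs rest
    stage2: _LinearStage            # T vs E
    n_train: int
    class_counts: dict
    explained_variance: float       # fraction captured by kept components

    def transform(self, fv: FeatureVector) -> np.ndarray:
        z = (fv.raw - self.feat_mean) / self.feat_scale
        p = (z - self.pca_mean) @ self.pca_components.T
        d = (fv.duration_ms - self.dur_mean) / self.dur_scale
        return np.concatenate([p, [d]])

    def save(self, path: str | Path) -> None:
        obj = {
            "feat_mean": self.feat_mean.tolist(),
            "feat_scale": self.feat_scale.tolist(),
            "pca_mean": self.pca_mean.tolist(),
            "pca_components": self.pca_components.tolist(),
            "dur_mean": self.dur_mean, "dur_scale": self.dur_scale,
            "stage1": {"coef": self.stage1.coef.tolist(),
                       "intercept": self.stage1.intercept,
                       "positive": self.stage1.positive_label,
                       "negative": self.stage1.negative_label},
            "stage2": {"coef": self.stage2.coef.tolist(),
                       "intercept": self.stage2.intercept,
                       "positive": self.stage2.positive_label,
                       "negative": self.stage2.negative_label},
            "n_train": self.n_train, "class_counts": self.class_counts,
            "explained_variance": self.explained_variance,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        o = json.loads(Path(path).read_text())
        def stage(d):
            return _LinearStage(np.asarray(d["coef"]), d["intercept"],
                                d["positive"], d["negative"])
        return cls(np.asarray(o["feat_mean"]), np.asarray(o["feat_scale"]),
                   np.asarray(o["pca_mean"]), np.asarray(o["pca_components"]),
                   o["dur_mean"], o["dur_scale"], stage(o["stage1"]),
                   stage(o["stage2"]), o["n_train"], o["class_counts"],
                   o["explained_variance"])


def _fit_linear_svm(x: np.ndarray, y: np.ndarray, positive: str,
                    negative: str, c: float, seed: int) -> _LinearStage:
    svm = SVC(kernel="linear", C=c, random_state=seed)
    svm.fit(x, y)
    coef = svm.coef_[0]
    intercept = float(svm.intercept_[0])
    # sklearn orders classes lexically; decision > 0 means classes_[1]
    pos = svm.classes_[1]
    if pos != positive:
        coef, intercept = -coef, -intercept
    return _LinearStage(coef, intercept, positive, negative)


def fit_model(features: list[FeatureVector], labels: list[str],
              cfg: CalibrationConfig, seed: int = 0) -> ClassifierModel:
    """Fit the PCA + two-stage linear-SVM categorizer."""
    labels = list(labels)
    counts = {c: labels.count(c) for c in CLASSES}
    if counts["S"] < 5 or (counts["T"] + counts["E"]) < 5:
        raise ValueError(f"insufficient training examples per class: {counts}")
    raw = np.stack([f.raw for f in features])
    dur = np.array([f.duration_ms for f in features])
    feat_mean = raw.mean(axis=0)
    feat_scale = raw.std(axis=0)
    feat_scale[feat_scale == 0] = 1.0
    z = (raw - feat_mean) / feat_scale
    pca = PCA(n_components=cfg.pca_components, random_state=seed)
    p = pca.fit_transform(z)
    dur_mean, dur_scale = float(dur.mean()), float(dur.std() or 1.0)
    x = np.column_stack([p, (dur - dur_mean) / dur_scale])
    y = np.asarray(labels)

    stage1 = _fit_linear_svm(x, np.where(y == "S", "S", "rest"),
                             positive="S", negative="rest",
                             c=cfg.svm_c, seed=seed)
    te = np.isin(y, ["T", "E"])
    if counts["T"] < 1 or counts["E"] < 1:
        raise ValueError("stage-2 training requires both T and E examples")
    stage2 = _fit_linear_svm(x[te], y[te], positive="T", negative="E",
                             c=cfg.svm_c, seed=seed)
    return ClassifierModel(
        feat_mean, feat_scale, pca.mean_.copy(), pca.components_.copy(),
        dur_mean, dur_scale, stage1, stage2, len(labels), counts,
        float(pca.explained_variance_ratio_.sum()))


def classify(model: ClassifierModel, fv: FeatureVector) -> str:
    """Two-stage decision: S or not; if not, T or E.

    A feature vector exactly on the stage-1 boundary is sent to stage 2
    (deterministic not-S tie rule).
    """
    x = model.transform(fv)
    if model.stage1.decide(x) == "S":
        return "S"
    return model.stage2.decide(x)
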