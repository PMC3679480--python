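import numpy as np
import pytest

from larvatrack import synth
from larvatrack.bouts import MovementEvent
from larvatrack.classify import (ClassifierModel, FeatureExtractionError,
                                 RAW_DIM, classify, extract_features,
                                 fit_model)
from larvatrack.synth import ARCHETYPES


def _movement(cfg, label, seed, noise=0.3):
    trace, track, ev = synth.synth_movement(ARCHETYPES[label], noise, seed, cfg)
    return extract_features(MovementEvent(0, 0, ev.start, ev.end),
                            trace, track, cfg)


@pytest.fixture(scope="module")
def training_set(cfg):
    feats, labels = [], []
    for j, label in enumerate("STE"):
        for k in range(40):
            feats.append(_movement(cfg, label, seed=j * 997 + k))
            labels.append(label)
    return feats, labels


class TestExtractFeatures:
    def test_raw_dimension_is_53(self, cfg):
        fv = _movement(cfg, "S", seed=1)
        assert fv.raw.shape == (RAW_DIM,) == (53,)

    def test_pure_sine_frequency_and_amplitude_bins(self, cfg):
        fs = cfg.frame_rate_hz
        n = int(round(0.4 * fs))
        t = np.arange(n) / fs
        trace = 20 * np.sin(2 * np.pi * 25 * t)
        track = np.tile([50.0, 50.0], (n, 1))        # stationary core
        fv = extract_features(MovementEvent(0, 0, 0, n - 1), trace, track, cfg)
        amp, freq, cum, speed = np.split(fv.raw, [15, 29, 43])
        assert np.allclose(freq, 25.0, rtol=0.1)
        assert amp.max() <= 20.5 and amp.max() > 15.0
        assert np.allclose(speed, 0.0)

    def test_short_event_padded_and_flagged(self, cfg):
        fs = cfg.frame_rate_hz
        n = int(round(0.08 * fs))                    # 80 ms event
        trace = 20 * np.sin(2 * np.pi * 25 * np.arange(n) / fs)
        track = np.zeros((n, 2))
        fv = extract_features(MovementEvent(0, 0, 0, n - 1), trace, track, cfg)
        assert fv.padded
        assert np.isfinite(fv.raw).all()

    def test_no_extremum_raises(self, cfg):
        with pytest.raises(FeatureExtractionError):
            extract_features(MovementEvent(0, 0, 0, 49), np.zeros(50),
                             np.zeros((50, 2)), cfg)


class TestFitAndClassify:
    def test_separable_training_accuracy_100(self, cfg, training_set):
        feats, labels = training_set
        model = fit_model(feats, labels, cfg, seed=0)
        pred = [classify(model, f) for f in feats]
        assert np.mean([p == y for p, y in zip(pred, labels)]) == 1.0

    def test_refit_deterministic(self, cfg, training_set):
        feats, labels = training_set
        m1 = fit_model(feats, labels, cfg, seed=3)
        m2 = fit_model(feats, labels, cfg, seed=3)
        assert np.array_equal(m1.stage1.coef, m2.stage1.coef)
        assert np.array_equal(m1.stage2.coef, m2.stage2.coef)
        assert np.array_equal(m1.pca_components, m2.pca_components)

    def test_explained_variance_reported(self, cfg, training_set):
        feats, labels = training_set
        model = fit_model(feats, labels, cfg, seed=0)
        assert model.pca_components.shape == (14, 53)
        assert model.explained_variance >= 0.8

    def test_missing_class_rejected(self, cfg, training_set):
        feats, labels = training_set
        only_s = [f for f, y in zip(feats, labels) if y == "S"]
        with pytest.raises(ValueError):
            fit_model(only_s, ["S"] * len(only_s), cfg, seed=0)

    def test_mirror_invariance(self, cfg):
        # flipping the larva left-right negates the bend trace; features
        # use |angle| so the decision must not change
        trace, track, ev = synth.synth_movement(ARCHETYPES["T"], 0.2, 42, cfg)
        mev = MovementEvent(0, 0, ev.start, ev.end)
        f1 = extract_features(mev, trace, track, cfg)
        f2 = extract_features(mev, -trace, track, cfg)
        assert np.allclose(f1.raw, f2.raw)

    def test_model_json_roundtrip(self, cfg, training_set, tmp_path):
        feats, labels = training_set
        model = fit_model(feats, labels, cfg, seed=0)
        model.save(tmp_path / "m.json")
        loaded = ClassifierModel.load(tmp_path / "m.json")
        for f in feats[:20]:
            assert classify(model, f) == classify(loaded, f)

    def test_class_proportions_recovered(self, cfg, training_set):
        feats, labels = training_set
        model = fit_model(feats, labels, cfg, seed=0)
        planted = {"S": 0.5, "T": 0.3, "E": 0.2}
        rng = np.random.default_rng(8)
        draws = rng.choice(list(planted), p=list(planted.values()), size=200)
        pred = [classify(model, _movement(cfg, y, seed=5000 + i))
                for i, y in enumerate(draws)]
        for c, p in planted.items():
            got = np.mean([x == c for x in pred])
            want = np.mean(draws == c)
            assert abs(got - want) <= 0.03
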