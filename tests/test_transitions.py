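import itertools

import numpy as np
import pandas as pd
import pytest

from larvatrack import benchmarks, transitions as tr
from larvatrack.transitions import (CLASSES, permutation_test,
                                    transition_index, windowed_index)


def _movements(labels, larva_ids=None, well=0, dt=1.0):
    n = len(labels)
    if larva_ids is None:
        larva_ids = [0] * n
    return pd.DataFrame({
        "well": well, "larva_id": larva_ids, "t_s": np.arange(n) * dt,
        "x_mm": np.linspace(0, 1, n), "y_mm": 0.0, "label": list(labels)})


def test_all_same_label_degenerate_index_is_one():
    index, _ = transition_index(_movements("SSSSS"), "same")
    assert index.loc["S", "S"] == pytest.approx(1.0)


def test_alternating_chain_index_two():
    index, _ = transition_index(_movements("ST" * 5), "same")
    assert index.loc["S", "T"] == pytest.approx(2.0)


def test_matches_exhaustive_enumeration_on_short_sequences():
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = int(rng.integers(2, 11))
        labels = rng.choice(list(CLASSES), size=n)
        df = _movements(labels)
        index, _ = transition_index(df, "same")
        pairs = list(zip(labels[:-1], labels[1:]))
        for b1, b2 in itertools.product(CLASSES, CLASSES):
            n_b1 = sum(1 for a, _ in pairs if a == b1)
            marginal = np.mean(labels == b2)
            if n_b1 == 0 or marginal == 0:
                assert np.isnan(index.loc[b1, b2])
            else:
                expected = (sum(1 for a, b in pairs if (a, b) == (b1, b2))
                            / n_b1) / marginal
                assert index.loc[b1, b2] == pytest.approx(expected, abs=1e-12)


def test_weighted_row_sums_to_one():
    rng = np.random.default_rng(1)
    labels = rng.choice(list(CLASSES), size=400, p=[0.5, 0.3, 0.2])
    df = _movements(labels, larva_ids=rng.integers(0, 4, 400))
    for variant in ("same", "different"):
        index, counts = transition_index(df, variant)
        marginal = {c: np.mean(labels == c) for c in CLASSES}
        for b1 in CLASSES:
            if counts.loc[b1].sum() == 0:
                continue
            total = sum(index.loc[b1, b2] * marginal[b2] for b2 in CLASSES)
            assert total == pytest.approx(1.0, abs=1e-9)


def test_iid_sequences_converge_to_one(cfg):
    out = benchmarks.transition_null(cfg, n=10_000, seed=2)
    for variant in ("same", "different"):
        assert out[variant]["max_sigma"] < 4.0


def test_single_window_successor_mode_matches_plain_index():
    rng = np.random.default_rng(3)
    labels = rng.choice(list(CLASSES), size=200)
    df = _movements(labels, larva_ids=rng.integers(0, 3, 200), dt=0.5)
    for variant in ("same", "different"):
        plain, counts = transition_index(df, variant)
        grids = windowed_index(df, [0.0, 1e9], [0.0, 1e9], variant,
                               min_count=1, pairing="successor")
        for g in grids:
            b1, b2 = g.pair
            if counts.loc[b1].sum() == 0:
                continue
            assert g.index[0, 0] == pytest.approx(plain.loc[b1, b2], abs=1e-12)


def test_cross_well_movements_never_paired():
    df = pd.concat([
        _movements("STE" * 4, well=0, larva_ids=[0, 1] * 6),
        _movements("ETS" * 4, well=1, larva_ids=[2, 3] * 6),
    ], ignore_index=True)
    pairs = tr.windowed_pairs(df, "different", t_max=100.0)
    wells = df["well"].to_numpy()
    assert len(pairs) > 0
    assert (wells[pairs[:, 0]] == wells[pairs[:, 1]]).all()


def test_planted_enrichment_recovered(cfg):
    out = benchmarks.transition_planted(cfg, n=8000, seed=5,
                                        n_permutations=30)
    assert out["i_max"] == pytest.approx(3.0, abs=0.4)
    assert out["p_ttest"] < 0.01


def test_permutation_deterministic_given_seed(cfg):
    df = _movements(np.random.default_rng(0).choice(list(CLASSES), 300),
                    dt=0.5)
    kw = dict(t_edges=[0, 1, 2], d_edges=[0, 5], n_permutations=20,
              min_count=5)
    r1 = permutation_test(df, ("E", "E"), "same", seed=7, **kw)
    r2 = permutation_test(df, ("E", "E"), "same", seed=7, **kw)
    assert np.array_equal(r1.null_values, r2.null_values)
    assert r1.p_ttest == r2.p_ttest


def test_permutation_calibrated_on_random_labels(cfg):
    # on label-shuffled data the observed maximum should rarely look
    # significant
    rng = np.random.default_rng(11)
    n_ok = 0
    for rep in range(10):
        labels = rng.choice(list(CLASSES), size=250,
                            p=benchmarks._marginal_p())
        df = _movements(labels, larva_ids=rng.integers(0, 5, 250), dt=0.4)
        res = permutation_test(df, ("E", "E"), "same", [0, 1, 2], [0, 5],
                               n_permutations=30, seed=rep, min_count=5)
        if not np.isfinite(res.observed) or res.p_ttest > 0.05:
            n_ok += 1
    assert n_ok >= 9


def test_fewer_than_two_movements_empty():
    df = _movements("S")
    index, counts = transition_index(df, "same")
    assert counts.to_numpy().sum() == 0
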