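"""Markov-chain analysis of maneuver sequences: the transition index.

For two maneuver classes B1, B2 the transition index is

    I(B1 -> B2) = p(second = B2 | first = B1) / p(B2)

over pairs of sequential movements in a well; I = 1 when the order of
maneuvers is random, I > 1 when B2 follows B1 more often than chance.
Pairs are split into a same-larva variant (consecutive movements of one
larva) and a different-larva variant (consecutive movements well-wide,
restricted to two distinct larvae).  The windowed form restricts the
conditional to pairs whose onset-time difference and onset-position
distance fall in a (time, distance) cell, keeping the marginal p(B2)
partition-wide; significance of the maximal cell value is assessed by
label permutation.

Movements are passed as a pandas DataFrame with columns
``well, larva_id, t_s, x_mm, y_mm, label``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

CLASSES = ("S", "T", "E")
REQUIRED = ["well", "larva_id", "t_s", "x_mm", "y_mm", "label"]

__all__ = ["TransitionIndexGrid", "PermutationResult", "sequential_pairs",
           "windowed_pairs", "transition_index", "windowed_index",
           "permutation_test", "CLASSES"]


@dataclasses.dataclass
class TransitionIndexGrid:
    pair: tuple[str, str]
    variant: str                  # 'same' or 'different'
    t_edges: np.ndarray
    d_edges: np.ndarray
    index: np.ndarray             # (n_t, n_d), NaN where masked
    counts: np.ndarray            # per-cell pair counts for this B1

    @property
    def i_max(self) -> float:
        return float(np.nanmax(self.index)) if np.isfinite(self.index).any() else np.nan


@dataclasses.dataclass
class PermutationResult:
    pair: tuple[str, str]
    variant: str
    observed: float
    null_values: np.ndarray
    p_ttest: float
    p_exceedance: float
    null_mean: float
    null_sd: float


def _check(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"movements table missing columns {missing}")
    bad = set(df["label"]) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown maneuver labels {sorted(bad)}")
    return df.sort_values(["well", "t_s"], kind="stable").reset_index(drop=True)


# ----------------------------------------------------------------------
def sequential_pairs(df: pd.DataFrame, variant: str) -> np.ndarray:
    """Indices (n, 2) of sequential movement pairs for one variant."""
    df = _check(df)
    pairs = []
    if variant == "same":
        for _, g in df.groupby(["well", "larva_id"], sort=False):
            idx = g.index.to_numpy()
            pairs.append(np.column_stack([idx[:-1], idx[1:]]))
    elif variant == "different":
        for _, g in df.groupby("well", sort=False):
            idx = g.index.to_numpy()
            a, b = idx[:-1], idx[1:]
            keep = df["larva_id"].to_numpy()[a] != df["larva_id"].to_numpy()[b]
            pairs.append(np.column_stack([a[keep], b[keep]]))
    else:
        raise ValueError("variant must be 'same' or 'different'")
    return np.vstack(pairs) if pairs else np.empty((0, 2), dtype=int)


def transition_index(df: pd.DataFrame, variant: str = "same",
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """3x3 transition-index matrix over all sequential pairs.

    Returns (I, counts) as label-indexed DataFrames; cells whose B1 never
    occurs as a first movement are NaN.  The marginal p(B2) is computed
    over all movements in the table.
    """
    df = _check(df)
    pairs = sequential_pairs(df, variant)
    labels = df["label"].to_numpy()
    marginal = {c: (labels == c).mean() for c in CLASSES}
    counts = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    for a, b in pairs:
        counts.loc[labels[a], labels[b]] += 1
    index = pd.DataFrame(np.nan, index=list(CLASSES), columns=list(CLASSES))
    for b1 in CLASSES:
        row = counts.loc[b1].to_numpy()
        if row.sum() == 0:
            continue
        for b2 in CLASSES:
            if marginal[b2] > 0:
                index.loc[b1, b2] = (counts.loc[b1, b2] / row.sum()) / marginal[b2]
    return index, counts


# ----------------------------------------------------------------------
def windowed_pairs(df: pd.DataFrame, variant: str, t_max: float,
                   pairing: str = "all") -> np.ndarray:
    """Ordered movement pairs within a well for the windowed index.

    ``pairing='all'``: every ordered pair with onset-time difference in
    (0, t_max].  ``pairing='successor'``: only sequential pairs (as in
    :func:`sequential_pairs`) falling inside the time window.
    """
    df = _check(df)
    if pairing == "successor":
        pairs = sequential_pairs(df, variant)
        if len(pairs) == 0:
            return pairs
        t = df["t_s"].to_numpy()
        dt = t[pairs[:, 1]] - t[pairs[:, 0]]
        return pairs[(dt > 0) & (dt <= t_max) | (dt == 0)]
    if pairing != "all":
        raise ValueError("pairing must be 'all' or 'successor'")
    out = []
    larva = df["larva_id"].to_numpy()
    for _, g in df.groupby("well", sort=False):
        idx = g.index.to_numpy()
        t = g["t_s"].to_numpy()
        hi = np.searchsorted(t, t + t_max, side="right")
        for k, i in enumerate(idx):
            js = idx[k + 1:hi[k]]
            if variant == "same":
                js = js[larva[js] == larva[i]]
            else:
                js = js[larva[js] != larva[i]]
            if js.size:
                out.append(np.column_stack([np.full(js.size, i), js]))
    return np.vstack(out) if out else np.empty((0, 2), dtype=int)


def _grid_from_pairs(df: pd.DataFrame, pairs: np.ndarray, labels: np.ndarray,
                     pair_labels: tuple[str, str], t_edges, d_edges,
                     min_count: int) -> tuple[np.ndarray, np.ndarray]:
    t_edges = np.asarray(t_edges, dtype=float)
    d_edges = np.asarray(d_edges, dtype=float)
    b1, b2 = pair_labels
    marginal = float((labels == b2).mean())
    nt, nd = len(t_edges) - 1, len(d_edges) - 1
    index = np.full((nt, nd), np.nan)
    counts = np.zeros((nt, nd), dtype=int)
    if len(pairs) == 0 or marginal == 0:
        return index, counts
    t = df["t_s"].to_numpy()
    xy = df[["x_mm", "y_mm"]].to_numpy()
    a, b = pairs[:, 0], pairs[:, 1]
    first_is_b1 = labels[a] == b1
    dt = t[b] - t[a]
    dd = np.hypot(*(xy[b] - xy[a]).T)
    it = np.searchsorted(t_edges, dt, side="right") - 1
    idd = np.searchsorted(d_edges, dd, side="right") - 1
    ok = (it >= 0) & (it < nt) & (idd >= 0) & (idd < nd) & first_is_b1
    second_is_b2 = labels[b] == b2
    for ti in range(nt):
        for di in range(nd):
            cell = ok & (it == ti) & (idd == di)
            n = int(cell.sum())
            counts[ti, di] = n
            if n >= min_count:
                index[ti, di] = (second_is_b2[cell].mean()) / marginal
    return index, counts


def windowed_index(df: pd.DataFrame, t_edges, d_edges, variant: str = "same",
                   pair: tuple[str, str] | None = None,
                   min_count: int = 20,
                   pairing: str = "all") -> list[TransitionIndexGrid]:
    """Transition-index grids over (time, distance) windows.

    Returns one grid per maneuver pair (all nine, or just ``pair``).
    Cells with fewer than ``min_count`` pairs are masked (NaN).
    """
    t_edges = np.asarray(t_edges, dtype=float)
    d_edges = np.asarray(d_edges, dtype=float)
    if len(t_edges) < 2 or len(d_edges) < 2:
        raise ValueError("need at least one time and one distance window")
    df = _check(df)
    pairs = windowed_pairs(df, variant, float(t_edges[-1]), pairing)
    labels = df["label"].to_numpy()
    wanted = [pair] if pair is not None else [
        (b1, b2) for b1 in CLASSES for b2 in CLASSES]
    grids = []
    for pl in wanted:
        index, counts = _grid_from_pairs(df, pairs, labels, pl,
                                         t_edges, d_edges, min_count)
        grids.append(TransitionIndexGrid(pl, variant, t_edges, d_edges,
                                         index, counts))
    return grids


# ----------------------------------------------------------------------
def permutation_test(df: pd.DataFrame, pair: tuple[str, str], variant: str,
                     t_edges, d_edges, n_permutations: int = 50,
                     seed: int = 0, min_count: int = 20,
                     pairing: str = "all") -> PermutationResult:
    """Permutation test for the maximal windowed transition index.

    Maneuver labels are shuffled across movements while identities, times
    and positions stay fixed; I_max is recomputed per permutation.  The
    observed I_max is compared to the permutation sample with a two-sample
    t-test in which the observed side has a single value (pooled variance
    comes entirely from the permutation sample, standard error
    ``sd * sqrt(1 + 1/n)``, n-1 degrees of freedom); an exceedance-count
    p-value is reported alongside as a distribution-free check.
    """
    df = _check(df)
    rng = np.random.default_rng(seed)
    observed = windowed_index(df, t_edges, d_edges, variant, pair,
                              min_count, pairing)[0].i_max
    labels = df["label"].to_numpy().copy()
    null = np.empty(n_permutations)
    work = df.copy()
    for i in range(n_permutations):
        work["label"] = rng.permutation(labels)
        null[i] = windowed_index(work, t_edges, d_edges, variant, pair,
                                 min_count, pairing)[0].i_max
    finite = null[np.isfinite(null)]
    null_mean = float(finite.mean()) if finite.size else float("nan")
    null_sd = float(finite.std(ddof=1)) if finite.size > 1 else float("nan")
    if null_sd == 0 or not np.isfinite(null_sd):
        p_t = 0.0 if observed > null_mean else 1.0
    else:
        n_f = len(finite)
        se = null_sd * np.sqrt(1.0 + 1.0 / n_f)
        t_stat = (observed - null_mean) / se
        p_t = float(2.0 * stats.t.sf(abs(t_stat), df=n_f - 1))
    p_exc = float((1 + np.sum(finite >= observed)) / (len(finite) + 1))
    return PermutationResult(pair, variant, observed, null, p_t, p_exc,
                             null_mean, null_sd)
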