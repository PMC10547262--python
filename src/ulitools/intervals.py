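"""Genomic interval utilities (0-based, half-open) used by the contact screen.

Intervals are plain pandas DataFrames with columns ``chrom``, ``start``,
``end`` and optional ``score``/``label`` columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "sort_intervals",
    "merge_cres",
    "overlap_flags",
    "annotate_neighbors",
    "split_quartiles",
    "midpoints",
]

NEIGHBOR_GROUPS = ("0", "1-4", "5-10", ">=10")


def _check(df: pd.DataFrame) -> None:
    if not {"chrom", "start", "end"}.issubset(df.columns):
        raise ValueError("intervals need chrom/start/end columns")
    if np.any(df["start"].to_numpy() >= df["end"].to_numpy()):
        bad = int(np.flatnonzero(df["start"].to_numpy() >= df["end"].to_numpy())[0])
        raise ValueError(f"interval row {bad}: start >= end")


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def midpoints(df: pd.DataFrame) -> np.ndarray:
    """Integer midpoints, floor((start + end) / 2)."""
    return ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)


def merge_cres(peaks: pd.DataFrame, gap: int = 5000) -> pd.DataFrame:
    """Merge overlapping peaks and peaks separated end-to-start by < gap bp."""
    _check(peaks)
    peaks = sort_intervals(peaks)
    out = []
    for chrom, grp in peaks.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        run_end = np.maximum.accumulate(ends)
        # new cluster wherever the gap to the previous running end is >= gap
        new = np.ones(len(grp), dtype=bool)
        new[1:] = starts[1:] - run_end[:-1] >= gap
        cluster = np.cumsum(new) - 1
        n_clusters = int(cluster[-1]) + 1
        # sorted by start, so each cluster's first member has the min start
        mstart = starts[new]
        mend = np.zeros(n_clusters, dtype=np.int64)
        np.maximum.at(mend, cluster, ends)
        out.append(pd.DataFrame({"chrom": chrom, "start": mstart, "end": mend}))
    return pd.concat(out, ignore_index=True)


def overlap_flags(cres: pd.DataFrame, factor_peaks: pd.DataFrame) -> np.ndarray:
    """True for each CRE overlapped by >= 1 bp of any factor peak (half-open)."""
    _check(cres)
    flags = np.zeros(len(cres), dtype=bool)
    if len(factor_peaks) == 0:
        return flags
    _check(factor_peaks)
    merged = merge_cres(factor_peaks, gap=0)  # gap 0: merge only true overlaps
    for chrom, grp in merged.groupby("chrom", sort=False):
        sel = np.flatnonzero(cres["chrom"].to_numpy() == chrom)
        if len(sel) == 0:
            continue
        p_start = grp["start"].to_numpy()
        p_end = grp["end"].to_numpy()
        c_start = cres["start"].to_numpy()[sel]
        c_end = cres["end"].to_numpy()[sel]
        # merged peaks are sorted & disjoint: the only candidate overlapping
        # [c_start, c_end) is the last peak with p_start < c_end
        idx = np.searchsorted(p_start, c_end, side="left") - 1
        ok = idx >= 0
        hit = np.zeros(len(sel), dtype=bool)
        hit[ok] = p_end[idx[ok]] > c_start[ok]
        flags[sel] = hit
    return flags


def annotate_neighbors(peaks: pd.DataFrame, min_gap: int = 2500,
                       window: int = 100000) -> pd.DataFrame:
    """Count nearby peaks per peak and bin the counts into groups.

    Distance between two peaks is the end-to-start gap (0 if they overlap).
    Neighbors at distance < min_gap are discarded; neighbors with
    min_gap <= distance < window are counted. Groups: 0, 1-4, 5-10
    (counts 5..9), >=10.
    """
    _check(peaks)
    peaks = sort_intervals(peaks)
    counts = np.zeros(len(peaks), dtype=np.int64)
    offset = 0
    for _, grp in peaks.groupby("chrom", sort=False):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        n = len(grp)
        for k in range(n):
            gapd = np.maximum(0, np.maximum(s - e[k], s[k] - e))
            gapd[k] = -1  # self, excluded below
            counts[offset + k] = int(np.sum((gapd >= min_gap) & (gapd < window)))
        offset += n
    group = np.select(
        [counts == 0, counts <= 4, counts < 10],
        [NEIGHBOR_GROUPS[0], NEIGHBOR_GROUPS[1], NEIGHBOR_GROUPS[2]],
        default=NEIGHBOR_GROUPS[3])
    out = peaks.copy()
    out["n_neighbors"] = counts
    out["neighbor_group"] = group
    return out


def split_quartiles(regions: pd.DataFrame, score: np.ndarray | str = "score") -> np.ndarray:
    """Quartile label per region by score rank; Q4 = highest scores.

    Ties are broken by stable genome-order rank so assignment is
    deterministic.
    """
    if isinstance(score, str):
        score = regions[score].to_numpy()
    score = np.asarray(score, dtype=float)
    if len(score) < 4:
        raise ValueError("need at least 4 regions to split into quartiles")
    if not np.all(np.isfinite(score)):
        raise ValueError("scores must be finite")
    order = np.argsort(score, kind="stable")
    rank = np.empty(len(score), dtype=np.int64)
    rank[order] = np.arange(len(score))
    q = (4 * rank) // len(score)  # 0..3
    return np.array([f"Q{int(v) + 1}" for v in q])
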