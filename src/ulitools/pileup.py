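"""Distance-stratified average O/E pileups, corner normalization, stripes.

A "snip" is a square window of O/E values centered on the pixel joining two
region midpoints (rows follow the lower-coordinate anchor). Snips are
averaged pixel-wise per separation stratum, optionally rescaled by the mean
of the two diagonal-direction background corner blocks, and individual
pairs can be inspected through their L-shaped "corner stripe" through the
central pixel or the distribution of central-pixel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactMatrix, OEMatrix

__all__ = [
    "PileupConfig",
    "Pileup",
    "snip_oe_window",
    "snip_pairs",
    "aggregate_pileup",
    "corner_normalize",
    "cross_group_pileup",
    "extract_corner_stripes",
    "central_pixel_ecdf",
    "shifted_control_pileup",
]

DEFAULT_PILEUP_BREAKS = (100_000, 1_000_000, 10_000_000, 25_000_000, 100_000_000)


@dataclass
class PileupConfig:
    flank: int = 100_000
    resolution: int = 5_000
    min_sep: int = 100_000
    max_sep: int = 100_000_000
    breaks: tuple = DEFAULT_PILEUP_BREAKS
    corner_size: int = 10
    normalization: str = "expected"  # expected | shifted-controls | none

    def __post_init__(self):
        if self.flank % self.resolution != 0:
            raise ValueError("flank must be divisible by resolution")
        if list(self.breaks) != sorted(self.breaks):
            raise ValueError("strata breaks must be ascending")

    @property
    def flank_bins(self) -> int:
        return self.flank // self.resolution

    @property
    def grid_side(self) -> int:
        return 2 * self.flank_bins + 1

    def stratum_labels(self) -> list[str]:
        bks = self._full_breaks()
        return [f"{lo / 1e6:g}-{hi / 1e6:g}Mb" for lo, hi in zip(bks[:-1], bks[1:])]

    def _full_breaks(self) -> list[int]:
        bks = [b for b in self.breaks if self.min_sep <= b <= self.max_sep]
        if not bks or bks[0] != self.min_sep:
            bks = [self.min_sep, *bks]
        if bks[-1] != self.max_sep:
            bks = [*bks, self.max_sep]
        return bks

    def stratum_of(self, separations: np.ndarray) -> np.ndarray:
        bks = self._full_breaks()
        labels = self.stratum_labels()
        idx = np.searchsorted(bks, separations, side="right") - 1
        ok = (separations >= bks[0]) & (separations < bks[-1])
        out = np.array(labels + [""])[np.clip(idx, 0, len(labels))]
        out[~ok] = ""
        return out


@dataclass
class Pileup:
    """Per-stratum mean O/E grids with bookkeeping."""

    config: PileupConfig
    grids: dict = field(default_factory=dict)       # label -> (side, side) float
    n_pairs: dict = field(default_factory=dict)     # label -> int
    n_missing: dict = field(default_factory=dict)   # label -> per-pixel missing count
    n_skipped: int = 0                              # pairs whose window left the chromosome
    corner_means: dict = field(default_factory=dict)


def snip_oe_window(chrom: str, mid_a: int, mid_b: int, oe: OEMatrix,
                   config: PileupConfig) -> np.ndarray | None:
    """O/E window centered on (bin(mid_a), bin(mid_b)); None if out of bounds.

    Rows follow the upstream (lower-coordinate) anchor, columns the
    downstream one; missing pixels stay NaN.
    """
    if mid_a > mid_b:
        mid_a, mid_b = mid_b, mid_a
    s = oe.bins.chrom_slices[chrom]
    nb = s.stop - s.start
    fb = config.flank_bins
    ia = mid_a // oe.resolution
    ib = mid_b // oe.resolution
    if ia - fb < 0 or ib - fb < 0 or ia + fb >= nb or ib + fb >= nb:
        return None
    dense = oe.dense[chrom]
    return np.asarray(dense[ia - fb:ia + fb + 1, ib - fb:ib + fb + 1], dtype=np.float64)


def snip_pairs(pairs: pd.DataFrame, oe: OEMatrix, config: PileupConfig
               ) -> tuple[np.ndarray, np.ndarray, int]:
    """Snips for a pair table -> (stack, separations, n_skipped)."""
    snips, seps = [], []
    n_skipped = 0
    for chrom, mid_a, mid_b in zip(pairs["chrom"], pairs["mid_a"], pairs["mid_b"]):
        grid = snip_oe_window(chrom, int(mid_a), int(mid_b), oe, config)
        if grid is None:
            n_skipped += 1
            continue
        snips.append(grid)
        seps.append(abs(int(mid_b) - int(mid_a)))
    side = config.grid_side
    stack = np.array(snips) if snips else np.empty((0, side, side))
    return stack, np.array(seps, dtype=np.int64), n_skipped


def aggregate_pileup(snips: np.ndarray, separations: np.ndarray,
                     config: PileupConfig, n_skipped: int = 0) -> Pileup:
    """Pixel-wise mean over defined (non-NaN) values per separation stratum."""
    pile = Pileup(config=config, n_skipped=n_skipped)
    labels = config.stratum_labels()
    strata = config.stratum_of(separations)
    for label in labels:
        sel = strata == label
        pile.n_pairs[label] = int(sel.sum())
        if not sel.any():
            pile.grids[label] = np.full((config.grid_side,) * 2, np.nan)
            pile.n_missing[label] = np.zeros((config.grid_side,) * 2, dtype=np.int64)
            continue
        sub = snips[sel]
        with np.errstate(invalid="ignore"):
            pile.grids[label] = np.nanmean(sub, axis=0)
        pile.n_missing[label] = np.isnan(sub).sum(axis=0)
    return pile


def corner_normalize(obj, corner_size: int = 10):
    """Divide by the mean of the top-left and bottom-right corner blocks.

    These are the two blocks lying along the diagonal direction, i.e. the
    local background at the two anchors. Accepts a grid or a Pileup (all
    strata normalized; per-stratum corner means recorded).
    """
    if isinstance(obj, Pileup):
        out = Pileup(config=obj.config, n_pairs=dict(obj.n_pairs),
                     n_missing=dict(obj.n_missing), n_skipped=obj.n_skipped)
        for label, grid in obj.grids.items():
            if np.all(np.isnan(grid)):
                out.grids[label] = grid
                continue
            norm, cmean = _corner_normalize_grid(grid, corner_size)
            out.grids[label] = norm
            out.corner_means[label] = cmean
        return out
    norm, _ = _corner_normalize_grid(np.asarray(obj, dtype=float), corner_size)
    return norm


def _corner_normalize_grid(grid: np.ndarray, corner_size: int):
    cs = corner_size
    side = grid.shape[0]
    if 2 * cs >= side:
        raise ValueError(f"corner_size {cs} too large for grid side {side}")
    corners = np.concatenate([grid[:cs, :cs].ravel(), grid[-cs:, -cs:].ravel()])
    defined = corners[np.isfinite(corners)]
    if len(defined) == 0:
        raise ValueError("corner blocks contain no defined values")
    cmean = float(defined.mean())
    if cmean <= 0:
        raise ValueError(f"corner mean {cmean} is not positive; normalization refused")
    return grid / cmean, cmean


def cross_group_pileup(set_a: pd.DataFrame, set_b: pd.DataFrame, oe: OEMatrix,
                       config: PileupConfig) -> Pileup:
    """Pileup over A-B pairs only, oriented so set A always maps to rows.

    For pairs where B precedes A in the genome the snip is transposed, so
    the two genomic orders combine onto one oriented grid.
    """
    from .intervals import midpoints

    mids_a = midpoints(set_a)
    mids_b = midpoints(set_b)
    snips, seps = [], []
    n_skipped = 0
    for chrom in dict.fromkeys(set_a["chrom"]):
        am = mids_a[set_a["chrom"].to_numpy() == chrom]
        bm = mids_b[set_b["chrom"].to_numpy() == chrom]
        for ma in am:
            for mb in bm:
                sep = abs(int(mb) - int(ma))
                if not (config.min_sep <= sep < config.max_sep):
                    continue
                grid = snip_oe_window(chrom, int(ma), int(mb), oe, config)
                if grid is None:
                    n_skipped += 1
                    continue
                if mb < ma:  # B upstream: transpose so A stays on rows
                    grid = grid.T
                snips.append(grid)
                seps.append(sep)
    side = config.grid_side
    stack = np.array(snips) if snips else np.empty((0, side, side))
    return aggregate_pileup(stack, np.array(seps, dtype=np.int64), config, n_skipped)


def extract_corner_stripes(snips: np.ndarray) -> np.ndarray:
    """Per-pair L-shaped vector through the central pixel.

    Walks the central column from the top edge to the center, then the
    central row from the center to the right edge; length = grid side =
    2*flank_bins + 1, with the central pixel at the vector midpoint.
    """
    snips = np.asarray(snips)
    c = snips.shape[-1] // 2
    down_column = snips[..., : c + 1, c]
    right_row = snips[..., c, c + 1:]
    return np.concatenate([down_column, right_row], axis=-1)


def central_pixel_ecdf(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-group ECDF of central-pixel values; missing dropped.

    Returns a long table (group, value, ecdf) plus the exact-zero fraction
    per group in the ``zero_fraction`` column (constant within group).
    """
    rows = []
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) == 0:
            raise ValueError(f"group {name!r} has no defined values")
        v = np.sort(v)
        frac = np.arange(1, len(v) + 1) / len(v)
        zero_frac = float(np.mean(v == 0))
        rows.append(pd.DataFrame({"group": name, "value": v, "ecdf": frac,
                                  "zero_fraction": zero_frac}))
    return pd.concat(rows, ignore_index=True)


def shifted_control_pileup(pairs: pd.DataFrame, matrix: ContactMatrix,
                           config: PileupConfig, n_shifts: int = 5,
                           seed: int = 0) -> Pileup:
    """Pileup normalized by separation-matched random control windows.

    For each pair, ``n_shifts`` random same-chromosome pairs at the same
    separation are snipped from the balanced matrix; the reported grid is
    the mean observed balanced window divided by the mean control window,
    per stratum.
    """
    rng = np.random.default_rng(seed)
    if matrix.weights is None:
        raise ValueError("matrix must be balanced")
    bins = matrix.bins
    fb = config.flank_bins
    res = bins.resolution

    # dense balanced per chromosome (computed lazily per chrom)
    dense_cache: dict[str, np.ndarray] = {}

    def balanced_dense(chrom):
        if chrom not in dense_cache:
            s = bins.chrom_slices[chrom]
            w = matrix.weights[s]
            block = matrix.upper[s, s].toarray()
            bal = block * np.nan_to_num(w)[:, None] * np.nan_to_num(w)[None, :]
            bal = bal + np.triu(bal, 1).T
            invalid = ~np.isfinite(w)
            bal[invalid, :] = np.nan
            bal[:, invalid] = np.nan
            dense_cache[chrom] = bal
        return dense_cache[chrom]

    obs_sum: dict[str, np.ndarray] = {}
    obs_cnt: dict[str, np.ndarray] = {}
    ctl_sum: dict[str, np.ndarray] = {}
    ctl_cnt: dict[str, np.ndarray] = {}
    n_pairs: dict[str, int] = {}
    side = config.grid_side
    labels = config.stratum_labels()
    for lab in labels:
        obs_sum[lab] = np.zeros((side, side))
        obs_cnt[lab] = np.zeros((side, side), dtype=np.int64)
        ctl_sum[lab] = np.zeros((side, side))
        ctl_cnt[lab] = np.zeros((side, side), dtype=np.int64)
        n_pairs[lab] = 0

    n_skipped = 0
    for chrom, mid_a, mid_b in zip(pairs["chrom"], pairs["mid_a"], pairs["mid_b"]):
        mid_a, mid_b = int(min(mid_a, mid_b)), int(max(mid_a, mid_b))
        sep = mid_b - mid_a
        lab = config.stratum_of(np.array([sep]))[0]
        if not lab:
            continue
        dense = balanced_dense(chrom)
        nb = dense.shape[0]
        ia, ib = mid_a // res, mid_b // res
        if ia - fb < 0 or ib - fb < 0 or ia + fb >= nb or ib + fb >= nb:
            n_skipped += 1
            continue
        w = dense[ia - fb:ia + fb + 1, ib - fb:ib + fb + 1]
        ok = np.isfinite(w)
        obs_sum[lab][ok] += w[ok]
        obs_cnt[lab] += ok
        n_pairs[lab] += 1
        d = ib - ia
        lo, hi = fb, nb - fb - d
        if hi <= lo:
            continue
        for ja in rng.integers(lo, hi, size=n_shifts):
            cw = dense[ja - fb:ja + fb + 1, ja + d - fb:ja + d + fb + 1]
            cok = np.isfinite(cw)
            ctl_sum[lab][cok] += cw[cok]
            ctl_cnt[lab] += cok

    pile = Pileup(config=config, n_skipped=n_skipped)
    for lab in labels:
        pile.n_pairs[lab] = n_pairs[lab]
        with np.errstate(invalid="ignore", divide="ignore"):
            obs = obs_sum[lab] / obs_cnt[lab]
            ctl = ctl_sum[lab] / ctl_cnt[lab]
            pile.grids[lab] = obs / ctl
        pile.n_missing[lab] = np.zeros((side, side), dtype=np.int64)
    return pile
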