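"""Virtual Hi-C, virtual pileups, and virtual FISH from polymer trajectories.

Contacts and distances are computed on the simulated coordinates directly
(plain Euclidean geometry), so every observable is invariant under rigid
rotation and translation of a frame. Analyses conventionally use only the
second half of a trajectory (``Trajectory.second_half``), after the
bridging-induced clusters have formed.

Thresholds follow the virtual-microscopy conventions of the model: a
virtual Hi-C contact is two chromatin beads within 90 nm, binned at 7 beads
(21 kb); virtual pileups count contacts within 54 nm at single-bead (3 kb)
resolution; virtual FISH reports center-of-mass distances between 51-kb
(17-bead) windows and calls colocalization below 200 nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .polymer import Trajectory

__all__ = [
    "VirtualContactMap",
    "VirtualFISHResult",
    "virtual_hic",
    "virtual_pileup",
    "virtual_fish",
    "site_enrichment",
    "default_site_pairs",
]


@dataclass
class VirtualContactMap:
    """Cumulative integer contact counts between genomic bins of beads."""

    counts: np.ndarray      # (n_bins, n_bins) symmetric int64
    bin_beads: int
    bp_per_bead: int
    n_frames: int

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def add(self, other: "VirtualContactMap") -> "VirtualContactMap":
        if other.counts.shape != self.counts.shape or other.bin_beads != self.bin_beads:
            raise ValueError("incompatible virtual maps")
        return VirtualContactMap(self.counts + other.counts, self.bin_beads,
                                 self.bp_per_bead, self.n_frames + other.n_frames)


def virtual_hic(traj: Trajectory, threshold_nm: float = 90.0,
                bin_beads: int = 7) -> VirtualContactMap:
    """Accumulate bead-pair contacts (< threshold) into bead bins, per frame."""
    cfg = traj.config
    thr = cfg.binder_threshold_sigma(threshold_nm)
    n_bins = -(-cfg.n_beads // bin_beads)
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)
    for f in range(traj.n_frames):
        chrom = traj.chromatin(f)
        tree = cKDTree(chrom)
        pairs = tree.query_pairs(thr, output_type="ndarray")
        if len(pairs) == 0:
            continue
        bi = pairs[:, 0] // bin_beads
        bj = pairs[:, 1] // bin_beads
        lo = np.minimum(bi, bj)
        hi = np.maximum(bi, bj)
        np.add.at(counts, (lo, hi), 1)
    counts = counts + np.triu(counts, 1).T
    return VirtualContactMap(counts=counts, bin_beads=bin_beads,
                             bp_per_bead=cfg.bp_per_bead, n_frames=traj.n_frames)


def virtual_pileup(traj: Trajectory, threshold_nm: float = 54.0,
                   flank_beads: int = 15, min_sep_beads: int = 100,
                   site_pairs: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Cumulative contact-count grid around binding-site pairs.

    For each qualifying site pair (bead separation > min_sep_beads, full
    window on the polymer) and each frame, grid[di, dj] counts frames-times-
    windows where beads (a+di-flank, b+dj-flank) are within the contact
    distance. Values are raw counts. Returns (grid, n_pairs_used).
    """
    cfg = traj.config
    thr = cfg.binder_threshold_sigma(threshold_nm)
    sites = traj.site_map.indices
    if site_pairs is None:
        site_pairs = _qualifying_pairs(sites, cfg.n_beads, min_sep_beads, flank_beads)
    side = 2 * flank_beads + 1
    grid = np.zeros((side, side), dtype=np.int64)
    for f in range(traj.n_frames):
        chrom = traj.chromatin(f)
        for a, b in site_pairs:
            wa = chrom[a - flank_beads: a + flank_beads + 1]
            wb = chrom[b - flank_beads: b + flank_beads + 1]
            d2 = np.sum((wa[:, None, :] - wb[None, :, :]) ** 2, axis=-1)
            grid += (d2 < thr * thr)
    return grid, len(site_pairs)


def _qualifying_pairs(sites: np.ndarray, n_beads: int, min_sep_beads: int,
                      flank_beads: int) -> np.ndarray:
    pairs = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            a, b = int(sites[i]), int(sites[j])
            if b - a <= min_sep_beads:
                continue
            if a - flank_beads < 0 or b + flank_beads >= n_beads:
                continue
            pairs.append((a, b))
    return np.array(pairs, dtype=np.int64).reshape(-1, 2)


@dataclass
class VirtualFISHResult:
    pairs: np.ndarray            # (n_pairs, 2) bead indices
    separations_bp: np.ndarray   # (n_pairs,)
    distances_nm: np.ndarray     # (n_pairs, n_frames)
    colocalization_fraction: np.ndarray  # (n_pairs,) fraction < threshold
    threshold_nm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bead_a": self.pairs[:, 0], "bead_b": self.pairs[:, 1],
            "separation_bp": self.separations_bp,
            "n_frames": self.distances_nm.shape[1],
            "fraction_colocalized": self.colocalization_fraction,
        })


def virtual_fish(traj: Trajectory, site_pairs: np.ndarray,
                 window_kb: float = 51.0, threshold_nm: float = 200.0
                 ) -> VirtualFISHResult:
    """Center-of-mass distances between windows around two sites, per frame.

    The window spans ``window_kb`` of chromatin centered on each site (17
    beads at 3 kb/bead); pairs whose window would run off the polymer are
    dropped. Colocalization fraction = fraction of sampled distances below
    the threshold.
    """
    cfg = traj.config
    w_beads = int(round(window_kb * 1000 / cfg.bp_per_bead))
    half = w_beads // 2
    kept = []
    for a, b in np.asarray(site_pairs, dtype=np.int64):
        if a - half < 0 or b + half >= cfg.n_beads or a > b:
            continue
        kept.append((int(a), int(b)))
    if not kept:
        raise ValueError("no site pair admits a full window")
    kept = np.array(kept, dtype=np.int64)
    dists = np.empty((len(kept), traj.n_frames))
    for f in range(traj.n_frames):
        chrom = traj.chromatin(f)
        for k, (a, b) in enumerate(kept):
            com_a = chrom[a - half: a + half + 1].mean(axis=0)
            com_b = chrom[b - half: b + half + 1].mean(axis=0)
            dists[k, f] = np.linalg.norm(com_a - com_b)
    dists_nm = dists * cfg.sigma_nm
    frac = np.mean(dists_nm < threshold_nm, axis=1)
    return VirtualFISHResult(pairs=kept,
                             separations_bp=(kept[:, 1] - kept[:, 0]) * cfg.bp_per_bead,
                             distances_nm=dists_nm,
                             colocalization_fraction=frac,
                             threshold_nm=threshold_nm)


def site_bead_contact_enrichment(traj: Trajectory, threshold_nm: float = 90.0,
                                 min_sep_beads: int = 100) -> dict:
    """Bead-level site-pair contact enrichment vs matched background.

    Counts, over frames, contacts (< threshold) between site-bead pairs
    separated by more than ``min_sep_beads``, and compares them with
    separation-matched pairs of non-site beads: enrichment =
    total site-pair contacts / expected from the per-separation background
    contact rate. This is the per-run statistic for the bridging test; it
    avoids the ~50x dilution of binning site contacts into multi-bead bins.
    """
    cfg = traj.config
    thr = cfg.binder_threshold_sigma(threshold_nm)
    n_beads = cfg.n_beads
    is_site = np.zeros(n_beads, dtype=bool)
    is_site[traj.site_map.indices] = True

    site_counts: dict[int, np.ndarray] = {}
    bg_count_by_sep = np.zeros(n_beads, dtype=np.int64)
    site_total = 0
    for f in range(traj.n_frames):
        tree = cKDTree(traj.chromatin(f))
        pairs = tree.query_pairs(thr, output_type="ndarray")
        if len(pairs) == 0:
            continue
        i, j = pairs[:, 0], pairs[:, 1]
        sep = np.abs(j - i)
        far = sep > min_sep_beads
        i, j, sep = i[far], j[far], sep[far]
        both_site = is_site[i] & is_site[j]
        neither = ~is_site[i] & ~is_site[j]
        site_total += int(both_site.sum())
        np.add.at(bg_count_by_sep, sep[neither], 1)

    # separation multiset of qualifying site pairs, and background pair counts
    sites = traj.site_map.indices
    a, b = np.triu_indices(len(sites), k=1)
    site_seps = np.abs(sites[b] - sites[a])
    site_seps = site_seps[site_seps > min_sep_beads]
    # number of (i, i+d) pairs with neither bead a site
    ns = (~is_site).astype(np.float64)
    corr = np.correlate(ns, ns, mode="full")[n_beads - 1:]
    n_bg_pairs_by_sep = np.rint(corr).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        bg_rate = np.where(n_bg_pairs_by_sep > 0,
                           bg_count_by_sep / np.maximum(n_bg_pairs_by_sep, 1), np.nan)
    expected = np.nansum(bg_rate[site_seps])
    ratio = site_total / expected if expected > 0 else np.nan
    return {"enrichment": float(ratio), "site_contacts": int(site_total),
            "expected_contacts": float(expected),
            "n_site_pairs": int(len(site_seps)), "n_frames": traj.n_frames}


def default_site_pairs(traj: Trajectory, min_sep_beads: int = 100) -> np.ndarray:
    """All site-bead pairs separated by more than min_sep_beads."""
    sites = traj.site_map.indices
    a, b = np.meshgrid(sites, sites, indexing="ij")
    sel = (b - a) > min_sep_beads
    return np.stack([a[sel], b[sel]], axis=1)


def site_enrichment(vmap: VirtualContactMap, site_map, min_sep_bp: int,
                    n_beads: int) -> dict:
    """Homotypic / heterotypic site-bin contact enrichment vs matched background.

    Site bins are bins containing >= 1 binding site. Pairs beyond
    ``min_sep_bp`` are split into same-type (homotypic: the bins share a
    site color) and different-type pairs; each class's cumulative counts are
    compared with separation-matched non-site bin pairs: enrichment =
    sum(counts) / sum(expected), expected from the per-separation mean over
    non-site pairs. Self (same-bin) pairs are excluded.
    """
    bb = vmap.bin_beads
    n_bins = vmap.n_bins
    min_sep_bins = int(np.ceil(min_sep_bp / (bb * vmap.bp_per_bead)))

    type_sets = [set() for _ in range(n_bins)]
    for idx, t in zip(site_map.indices, site_map.types):
        type_sets[int(idx) // bb].add(int(t))
    is_site = np.array([len(s) > 0 for s in type_sets])

    ii, jj = np.triu_indices(n_bins, k=1)
    sep = jj - ii
    keep = sep >= min_sep_bins
    ii, jj, sep = ii[keep], jj[keep], sep[keep]
    counts = vmap.counts[ii, jj]

    both_site = is_site[ii] & is_site[jj]
    neither = ~is_site[ii] & ~is_site[jj]
    homo = np.array([both_site[k] and len(type_sets[ii[k]] & type_sets[jj[k]]) > 0
                     for k in range(len(ii))])
    hetero = both_site & ~homo

    # per-separation background mean over non-site pairs
    bg_mean = np.full(n_bins, np.nan)
    for d in np.unique(sep[neither]):
        bg_mean[d] = counts[neither & (sep == d)].mean()

    def _ratio(mask: np.ndarray) -> float:
        mask = mask & np.isfinite(bg_mean[sep])
        if not mask.any():
            return np.nan
        expected = bg_mean[sep[mask]].sum()
        return float(counts[mask].sum() / expected) if expected > 0 else np.nan

    return {
        "homotypic": _ratio(homo),
        "heterotypic": _ratio(hetero),
        "n_homotypic_pairs": int(homo.sum()),
        "n_heterotypic_pairs": int(hetero.sum()),
        "n_background_pairs": int(neither.sum()),
        "min_sep_bp": min_sep_bp,
    }
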