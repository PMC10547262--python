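"""Synthetic contact maps and peak sets with planted ultra-long-range structure.

The generator emulates, with known ground truth, the features the screen and
pileup stages measure on real binned contact data:

* per-chromosome power-law distance decay, ``lambda(d) = depth * d**-alpha``
  (d in bins, d >= 1), with Poisson-sampled counts;
* a set of "active anchor" CREs whose pairwise pixels carry a multiplicative
  central enrichment ``e`` and whose rows/columns carry a stripe factor
  ``s`` (applied when exactly one bin of a pixel holds an anchor);
* background CREs with no planted enrichment;
* factor peak sets: a planted factor binds anchor CREs with probability
  ``sensitivity`` (plus a small background-CRE rate), while a decoy binds
  every CRE with a fixed probability independent of anchor status and
  scatters extra peaks uniformly away from anchors.

Everything is driven by one seed and the truth is serialized alongside the
data, so recovery tests have exact labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .contacts import BinTable, ContactMatrix

__all__ = [
    "SyntheticTruth",
    "FactorSpec",
    "make_toy_assembly",
    "place_cres",
    "simulate_contact_map",
    "make_factor_peaks",
    "generate_dataset",
]


@dataclass
class FactorSpec:
    """Association of one synthetic factor with the planted anchors."""

    name: str
    kind: str = "planted"            # planted | decoy
    sensitivity: float = 0.9         # planted: P(peak at anchor CRE)
    background_rate: float = 0.05    # planted: P(peak at background CRE)
    cre_rate: float = 0.7            # decoy: P(peak at any CRE), anchor-independent
    n_noise_peaks: int = 0           # extra uniform peaks away from anchors
    class_annotation: str = "other"


@dataclass
class SyntheticTruth:
    """Planted structure: anchors, enrichment, decay, factor associations."""

    anchors: pd.DataFrame
    cres: pd.DataFrame
    anchor_flags: np.ndarray          # per-CRE: is a planted anchor
    enrichment: float = 2.0           # e, central multiplicative factor (>= 1)
    stripe: float = 1.4               # s, anchor row/column factor (>= 1)
    alpha: float = 1.0                # decay exponent (> 0)
    depth: float = 100.0              # lambda at d = 1 bin
    seed: int = 0
    factors: list = field(default_factory=list)

    def __post_init__(self):
        if self.enrichment < 1 or self.stripe < 1 or self.alpha <= 0:
            raise ValueError("need e >= 1, s >= 1, alpha > 0")

    def to_json(self, path) -> None:
        payload = {
            "enrichment": self.enrichment, "stripe": self.stripe,
            "alpha": self.alpha, "depth": self.depth, "seed": self.seed,
            "anchors": self.anchors.to_dict(orient="list"),
            "cres": self.cres.to_dict(orient="list"),
            "anchor_flags": self.anchor_flags.astype(int).tolist(),
            "factors": [asdict(f) for f in self.factors],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def make_toy_assembly(n_chroms: int, lengths, resolution: int) -> BinTable:
    """Dense bin table over ``n_chroms`` chromosomes (bin_index continues
    across chromosomes)."""
    if np.isscalar(lengths):
        lengths = [int(lengths)] * n_chroms
    if len(lengths) != n_chroms:
        raise ValueError("lengths must match n_chroms")
    return BinTable.from_chrom_lengths(
        {f"chr{k + 1}": int(L) for k, L in enumerate(lengths)}, resolution)


def place_cres(bins: BinTable, n_anchors: int, n_background: int, seed: int,
               cre_halfwidth: int = 1000, edge_bins: int = 25) -> tuple[pd.DataFrame, np.ndarray]:
    """Place anchor + background CREs at distinct bin centers per chromosome.

    One CRE per chosen bin (so screen pixels are unambiguous); anchors and
    background are drawn together and split at random. ``edge_bins`` keeps
    CREs away from chromosome ends so pileup windows fit.
    """
    rng = np.random.default_rng((seed, 11))
    n_ch = len(bins.chroms)
    per_anchor = _split_counts(n_anchors, n_ch)
    per_bg = _split_counts(n_background, n_ch)
    rows = []
    flags = []
    for k, chrom in enumerate(bins.chroms):
        nb = bins.n_bins_of(chrom)
        usable = np.arange(edge_bins, nb - edge_bins)
        n_total = per_anchor[k] + per_bg[k]
        if n_total > len(usable):
            raise ValueError(f"{chrom}: not enough bins for {n_total} CREs")
        chosen = np.sort(rng.choice(usable, size=n_total, replace=False))
        is_anchor = np.zeros(n_total, dtype=bool)
        is_anchor[rng.choice(n_total, size=per_anchor[k], replace=False)] = True
        mids = chosen * bins.resolution + bins.resolution // 2
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "start": mids - cre_halfwidth,
            "end": mids + cre_halfwidth,
        }))
        flags.append(is_anchor)
    cres = pd.concat(rows, ignore_index=True)
    return cres, np.concatenate(flags)


def _split_counts(total: int, n_groups: int) -> list[int]:
    base = total // n_groups
    out = [base] * n_groups
    for k in range(total - base * n_groups):
        out[k] += 1
    return out


def simulate_contact_map(bins: BinTable, truth: SyntheticTruth,
                         seed: int | None = None) -> ContactMatrix:
    """Poisson counts with power-law decay and planted anchor enrichment.

    Pixel intensity: ``depth * |i-j|**-alpha`` (cis, |i-j| >= 1), times
    ``e`` when both bins contain anchors, times ``s`` when exactly one
    does. Extra enriched counts are drawn as independent Poisson increments
    (Poisson additivity), so the total at an enriched pixel is exactly
    Poisson of the enriched intensity.
    """
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng((seed, 13))
    anchors_mid = ((truth.anchors["start"].to_numpy()
                    + truth.anchors["end"].to_numpy()) // 2)
    anchor_chrom = truth.anchors["chrom"].to_numpy()

    all_i, all_j, all_c = [], [], []
    for chrom in bins.chroms:
        s = bins.chrom_slices[chrom]
        nb = s.stop - s.start
        a_bins = np.unique((anchors_mid[anchor_chrom == chrom] // bins.resolution))
        is_anchor = np.zeros(nb, dtype=bool)
        is_anchor[a_bins] = True

        if truth.depth > 0:
            for d in range(1, nb):
                lam = truth.depth * float(d) ** (-truth.alpha)
                c = rng.poisson(lam, size=nb - d)
                nz = np.flatnonzero(c)
                if len(nz):
                    all_i.append(nz + s.start)
                    all_j.append(nz + d + s.start)
                    all_c.append(c[nz])
            # anchor-anchor extra: lambda * (e - 1)
            if truth.enrichment > 1 and len(a_bins) >= 2:
                ai, aj = np.meshgrid(a_bins, a_bins, indexing="ij")
                sel = aj > ai
                ai, aj = ai[sel], aj[sel]
                lam = truth.depth * (aj - ai).astype(float) ** (-truth.alpha)
                extra = rng.poisson(lam * (truth.enrichment - 1))
                nz = extra > 0
                if nz.any():
                    all_i.append(ai[nz] + s.start)
                    all_j.append(aj[nz] + s.start)
                    all_c.append(extra[nz])
            # stripe extra (exactly one anchor): lambda * (s - 1)
            if truth.stripe > 1 and len(a_bins) >= 1:
                others = np.flatnonzero(~is_anchor)
                for a in a_bins:
                    d_off = np.abs(others - a)
                    ok = d_off >= 1
                    o = others[ok]
                    lam = truth.depth * d_off[ok].astype(float) ** (-truth.alpha)
                    extra = rng.poisson(lam * (truth.stripe - 1))
                    nz = extra > 0
                    if nz.any():
                        all_i.append(np.minimum(a, o[nz]) + s.start)
                        all_j.append(np.maximum(a, o[nz]) + s.start)
                        all_c.append(extra[nz])

    n = bins.n_bins
    if all_i:
        i = np.concatenate(all_i)
        j = np.concatenate(all_j)
        c = np.concatenate(all_c).astype(np.float64)
    else:
        i = j = np.array([], dtype=np.int64)
        c = np.array([], dtype=np.float64)
    upper = sp.coo_matrix((c, (i, j)), shape=(n, n)).tocsr()
    upper.sum_duplicates()
    return ContactMatrix(bins, upper)


def make_factor_peaks(truth: SyntheticTruth, specs: list[FactorSpec],
                      bins: BinTable, seed: int | None = None,
                      peak_halfwidth: int = 100, exclusion: int = 10_000
                      ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Factor peak BED sets with controlled association to anchors.

    Planted factors place a peak at each anchor CRE with probability
    ``sensitivity`` and at background CREs with ``background_rate``. Decoys
    bind every CRE with probability ``cre_rate`` *independent of anchor
    status* (the null the screen must not reject). ``n_noise_peaks`` extra
    peaks per factor are scattered uniformly outside an exclusion zone
    around anchors. Identical seeds give identical output.
    """
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng((seed, 17))
    cres = truth.cres
    mids = ((cres["start"].to_numpy() + cres["end"].to_numpy()) // 2)
    chrom_arr = cres["chrom"].to_numpy()
    anchor_mids = {}
    for chrom in bins.chroms:
        sel = (truth.anchors["chrom"] == chrom).to_numpy()
        anchor_mids[chrom] = ((truth.anchors["start"].to_numpy()[sel]
                               + truth.anchors["end"].to_numpy()[sel]) // 2)

    peak_sets: dict[str, pd.DataFrame] = {}
    labels = []
    for spec in specs:
        if spec.kind == "planted":
            p_bind = np.where(truth.anchor_flags, spec.sensitivity, spec.background_rate)
        elif spec.kind == "decoy":
            p_bind = np.full(len(cres), spec.cre_rate)
        else:
            raise ValueError(f"unknown factor kind {spec.kind!r}")
        bound = rng.random(len(cres)) < p_bind
        rows = [pd.DataFrame({
            "chrom": chrom_arr[bound],
            "start": mids[bound] - peak_halfwidth,
            "end": mids[bound] + peak_halfwidth,
        })]
        if spec.n_noise_peaks > 0:
            per = _split_counts(spec.n_noise_peaks, len(bins.chroms))
            for k, chrom in enumerate(bins.chroms):
                clen = int(bins.df.loc[bins.df["chrom"] == chrom, "end"].max())
                placed = []
                guard = 0
                while len(placed) < per[k] and guard < 50 * per[k] + 100:
                    guard += 1
                    x = int(rng.integers(peak_halfwidth, clen - peak_halfwidth))
                    if np.all(np.abs(anchor_mids[chrom] - x) >= exclusion):
                        placed.append(x)
                placed = np.array(sorted(placed), dtype=np.int64)
                rows.append(pd.DataFrame({
                    "chrom": chrom,
                    "start": placed - peak_halfwidth,
                    "end": placed + peak_halfwidth,
                }))
        peaks = pd.concat(rows, ignore_index=True)
        peaks = peaks.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        peak_sets[spec.name] = peaks
        labels.append({"factor": spec.name, "kind": spec.kind,
                       "n_peaks": len(peaks),
                       "n_bound_cres": int(bound.sum())})
    return peak_sets, pd.DataFrame(labels)


def generate_dataset(seed: int, n_chroms: int = 3, chrom_length: int = 30_000_000,
                     resolution: int = 10_000, n_anchors: int = 300,
                     n_background: int = 1800, enrichment: float = 2.0,
                     stripe: float = 1.4, alpha: float = 1.0,
                     depth: float = 100.0, n_decoys: int = 10,
                     planted_sensitivity: float = 0.9):
    """One-call synthetic study: assembly, truth, contact map, factor peaks.

    Defaults mirror the screen-recovery study conditions: 3 chromosomes of
    30 Mb at 10-kb bins, 300 anchors among 2100 CREs, e = 2, s = 1.4,
    alpha = 1, depth 100 (one mean count per pixel at 1 Mb). The background
    CRE count sets the effective sample size of the decoy null (bound flags
    are shared across pairs, so F fluctuates with the number of CREs, not
    pairs).
    Returns (bins, truth, matrix, peak_sets, labels).
    """
    bins = make_toy_assembly(n_chroms, chrom_length, resolution)
    cres, flags = place_cres(bins, n_anchors, n_background, seed)
    # the planted factor also binds background CREs at a baseline rate, as a
    # real hit factor would; it must overlap >= min_regions CREs to enter the
    # screen at all, while staying strongly anchor-associated
    specs = [FactorSpec(name="planted", kind="planted",
                        sensitivity=planted_sensitivity, background_rate=0.2,
                        class_annotation="transcription cofactor")]
    for k in range(n_decoys):
        specs.append(FactorSpec(name=f"decoy{k + 1}", kind="decoy",
                                cre_rate=0.7, n_noise_peaks=100))
    truth = SyntheticTruth(anchors=cres[flags].reset_index(drop=True),
                           cres=cres, anchor_flags=flags,
                           enrichment=enrichment, stripe=stripe, alpha=alpha,
                           depth=depth, seed=seed, factors=specs)
    matrix = simulate_contact_map(bins, truth)
    peak_sets, labels = make_factor_peaks(truth, specs, bins)
    return bins, truth, matrix, peak_sets, labels
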