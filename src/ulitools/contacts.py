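"""Binned genome-wide contact matrices: loading, balancing, expected, O/E.

The central objects are :class:`BinTable` (a dense 0-based binning of one or
more chromosomes at fixed resolution), :class:`ContactMatrix` (upper-triangular
sparse counts over those bins with optional per-bin balancing weights), and
:class:`OEMatrix` (per-chromosome dense observed-over-expected values with NaN
marking undefined pixels).

Conventions
-----------
* Coordinates are 0-based half-open; a genomic point lands in bin
  ``floor(pos / resolution)``.
* Only the upper triangle (``i <= j``) is stored; queries are symmetric.
* Balanced value of a pixel is ``w_i * w_j * count``; masked bins carry
  NaN weights and are excluded from every average.
* Expected is computed per whole chromosome (cis, one value per diagonal
  offset) or per chromosome pair (trans, scalar).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "BinTable",
    "ContactMatrix",
    "ExpectedProfile",
    "OEMatrix",
    "BalanceResult",
    "load_contacts",
    "iterative_correction",
    "compute_expected",
    "observed_over_expected",
]


class BinTable:
    """Dense, contiguous, 0-based binning of chromosomes at fixed resolution.

    Parameters
    ----------
    df : DataFrame with columns ``chrom``, ``start``, ``end`` in genome order.
    resolution : bin size in bp. All bins except possibly the last per
        chromosome must have length == resolution.
    """

    def __init__(self, df: pd.DataFrame, resolution: int):
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"bin table needs columns {sorted(required)}")
        df = df.reset_index(drop=True)
        self.df = df
        self.resolution = int(resolution)
        self._validate()
        self.n_bins = len(df)
        self.chroms = list(dict.fromkeys(df["chrom"]))
        # contiguous index range per chromosome
        self.chrom_slices: dict[str, slice] = {}
        chrom_arr = df["chrom"].to_numpy()
        for chrom in self.chroms:
            idx = np.flatnonzero(chrom_arr == chrom)
            self.chrom_slices[chrom] = slice(int(idx[0]), int(idx[-1]) + 1)
        self._chrom_of = chrom_arr

    def _validate(self) -> None:
        res = self.resolution
        for chrom, grp in self.df.groupby("chrom", sort=False):
            start = grp["start"].to_numpy()
            end = grp["end"].to_numpy()
            if np.any(start >= end):
                raise ValueError(f"{chrom}: bin with start >= end")
            if np.any(start[1:] != end[:-1]) or start[0] != 0:
                raise ValueError(f"{chrom}: bins do not tile contiguously from 0")
            if np.any((end - start)[:-1] != res):
                raise ValueError(f"{chrom}: interior bin length != resolution")
            if (end - start)[-1] > res:
                raise ValueError(f"{chrom}: last bin longer than resolution")

    @classmethod
    def from_chrom_lengths(cls, lengths: dict[str, int], resolution: int) -> "BinTable":
        rows = []
        for chrom, length in lengths.items():
            if length <= 0:
                raise ValueError(f"{chrom}: non-positive length")
            starts = np.arange(0, length, resolution, dtype=np.int64)
            ends = np.minimum(starts + resolution, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return cls(pd.concat(rows, ignore_index=True), resolution)

    def chrom_of(self, bin_index: int) -> str:
        return self._chrom_of[bin_index]

    def n_bins_of(self, chrom: str) -> int:
        s = self.chrom_slices[chrom]
        return s.stop - s.start

    def bin_of(self, chrom: str, pos: int) -> int:
        """Global bin index containing genomic point ``pos`` (0-based)."""
        s = self.chrom_slices[chrom]
        local = pos // self.resolution
        if local < 0 or s.start + local >= s.stop:
            raise ValueError(f"position {chrom}:{pos} outside binned range")
        return s.start + int(local)

    def bins_of(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`bin_of`."""
        s = self.chrom_slices[chrom]
        local = np.asarray(positions) // self.resolution
        if np.any(local < 0) or np.any(s.start + local >= s.stop):
            raise ValueError(f"positions outside binned range on {chrom}")
        return (s.start + local).astype(np.int64)


@dataclass
class BalanceResult:
    """Outcome of iterative correction."""

    weights: np.ndarray          # NaN at masked bins
    converged: bool
    achieved_tol: float
    scope: str
    n_iter: int


class ContactMatrix:
    """Symmetric binned contact counts, stored as upper-triangular sparse.

    ``weights`` is a per-bin float array (NaN = masked bin) or None when the
    matrix is unbalanced; ``balancing_mode`` records the scope used.
    """

    def __init__(self, bins: BinTable, upper: sp.csr_matrix,
                 weights: np.ndarray | None = None, balancing_mode: str = "none"):
        self.bins = bins
        self.upper = upper.tocsr()
        self.upper.sum_duplicates()
        self.weights = weights
        self.balancing_mode = balancing_mode

    # -- queries ------------------------------------------------------------
    def value(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        return float(self.upper[i, j])

    def total_count(self) -> float:
        return float(self.upper.sum())

    def symmetric(self) -> sp.csr_matrix:
        """Full symmetric matrix (diagonal counted once)."""
        u = self.upper
        return u + u.T - sp.diags(u.diagonal())

    def chrom_block(self, chrom_a: str, chrom_b: str | None = None) -> sp.csr_matrix:
        sa = self.bins.chrom_slices[chrom_a]
        sb = self.bins.chrom_slices[chrom_b or chrom_a]
        return self.upper[sa, sb]

    def valid_bins(self) -> np.ndarray:
        """Boolean mask of bins with a defined (unmasked) weight."""
        if self.weights is None:
            return np.ones(self.bins.n_bins, dtype=bool)
        return np.isfinite(self.weights)

    def set_unit_weights(self) -> None:
        """Unit weights: downstream analysis runs on raw counts.

        Appropriate for synthetic maps generated without visibility bias,
        where iterative correction would absorb genuine planted enrichment
        (enriched rows really do have more counts) into the weights.
        """
        self.weights = np.ones(self.bins.n_bins)
        self.balancing_mode = "unit"

    def balance(self, scope: str = "total", **kwargs) -> BalanceResult:
        """Run :func:`iterative_correction` and store the weights in place."""
        result = iterative_correction(self, scope=scope, **kwargs)
        self.weights = result.weights
        self.balancing_mode = scope
        return result


def load_contacts(bin_source, triplet_source, resolution: int | None = None) -> ContactMatrix:
    """Build a :class:`ContactMatrix` from a bin table and (i, j, count) triplets.

    ``bin_source`` may be a BinTable, a DataFrame (chrom/start/end), or a TSV
    path; ``triplet_source`` a DataFrame (bin1_id/bin2_id/count), an (i,j,c)
    array, or a TSV path. Entries are canonicalized to ``i <= j``; duplicate
    pixels are summed.
    """
    if isinstance(bin_source, BinTable):
        bins = bin_source
    else:
        if isinstance(bin_source, (str,)) or hasattr(bin_source, "__fspath__"):
            bdf = pd.read_csv(bin_source, sep="\t", comment="#",
                              names=["chrom", "start", "end"], dtype={"chrom": str})
        else:
            bdf = bin_source
        if resolution is None:
            resolution = int((bdf["end"] - bdf["start"]).iloc[0])
        bins = BinTable(bdf, resolution)

    if isinstance(triplet_source, (str,)) or hasattr(triplet_source, "__fspath__"):
        tdf = pd.read_csv(triplet_source, sep="\t", comment="#",
                          names=["bin1_id", "bin2_id", "count"])
        i, j, c = (tdf[k].to_numpy() for k in ("bin1_id", "bin2_id", "count"))
    elif isinstance(triplet_source, pd.DataFrame):
        i = triplet_source["bin1_id"].to_numpy()
        j = triplet_source["bin2_id"].to_numpy()
        c = triplet_source["count"].to_numpy()
    else:
        arr = np.asarray(triplet_source)
        if arr.size == 0:
            arr = arr.reshape(0, 3)
        i, j, c = arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2]

    n = bins.n_bins
    bad = (i < 0) | (i >= n) | (j < 0) | (j >= n)
    if np.any(bad):
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"triplet row {row}: bin index ({i[row]}, {j[row]}) out of range [0, {n})")
    if np.any(np.asarray(c) < 0):
        row = int(np.flatnonzero(np.asarray(c) < 0)[0])
        raise ValueError(f"triplet row {row}: negative count {c[row]}")
    ii = np.minimum(i, j)
    jj = np.maximum(i, j)
    upper = sp.coo_matrix((np.asarray(c, dtype=np.float64), (ii, jj)), shape=(n, n)).tocsr()
    upper.sum_duplicates()
    return ContactMatrix(bins, upper)


# ---------------------------------------------------------------------------
# Iterative correction (ICE)
# ---------------------------------------------------------------------------

def _scope_matrix(matrix: ContactMatrix, scope: str) -> sp.csr_matrix:
    """Full symmetric matrix restricted to the pixels the scope counts."""
    sym = matrix.symmetric().tocoo()
    chrom_of = matrix.bins._chrom_of
    same = chrom_of[sym.row] == chrom_of[sym.col]
    if scope == "total":
        keep = np.ones(sym.nnz, dtype=bool)
    elif scope == "cis":
        keep = same
    elif scope == "trans":
        keep = ~same
    else:
        raise ValueError(f"unknown balancing scope {scope!r}")
    return sp.coo_matrix(
        (sym.data[keep], (sym.row[keep], sym.col[keep])), shape=sym.shape).tocsr()


def iterative_correction(matrix: ContactMatrix, scope: str = "total",
                         max_iter: int = 200, tol: float = 1e-5,
                         mad_filter: float = 5.0) -> BalanceResult:
    """ICE balancing: find weights equalizing per-bin weighted coverage.

    Coverage of bin *i* is ``sum_j w_i w_j c_ij`` over the pixels selected by
    ``scope`` (cis-only, everything, or trans-only). For ``scope='cis'`` each
    chromosome is balanced independently, mirroring cis-only balancing in
    standard Hi-C pipelines. On convergence, ``max |cov / mean(cov) - 1| <
    tol`` over unmasked bins and weights are rescaled so the mean weighted
    coverage equals 1.

    Bins with zero raw coverage, and bins whose log10 raw coverage lies more
    than ``mad_filter`` median-absolute-deviations below the median, are
    masked (NaN weight).
    """
    sym = _scope_matrix(matrix, scope)
    n = matrix.bins.n_bins
    raw_cov = np.asarray(sym.sum(axis=1)).ravel()

    mask = raw_cov <= 0
    pos = ~mask
    if pos.any() and mad_filter is not None and mad_filter > 0:
        logc = np.log10(raw_cov[pos])
        med = np.median(logc)
        mad = np.median(np.abs(logc - med))
        if mad > 0:
            low = np.zeros(n, dtype=bool)
            low[pos] = logc < med - mad_filter * mad
            mask |= low
    if mask.all():
        raise ValueError("no unmasked bins: cannot balance")

    if scope == "cis":
        groups = [matrix.bins.chrom_slices[c] for c in matrix.bins.chroms]
    else:
        groups = [slice(0, n)]

    w = np.ones(n)
    w[mask] = 0.0
    achieved = np.inf
    converged = True
    n_iter_total = 0
    for grp in groups:
        block = sym[grp, grp]
        wg = w[grp].copy()
        keep = wg > 0
        if not keep.any():
            continue
        achieved_g = np.inf
        ok = False
        it = 0
        for it in range(1, max_iter + 1):
            cov = wg * np.asarray(block @ wg).ravel()
            mean_cov = cov[keep].mean()
            if mean_cov <= 0:
                raise ValueError("zero mean coverage during balancing")
            rel = cov[keep] / mean_cov
            achieved_g = float(np.max(np.abs(rel - 1.0)))
            if achieved_g < tol:
                ok = True
                break
            wg[keep] /= rel
        # scale so mean weighted coverage is 1
        cov = wg * np.asarray(block @ wg).ravel()
        mean_cov = cov[keep].mean()
        if mean_cov > 0:
            wg[keep] /= np.sqrt(mean_cov)
        w[grp] = wg
        achieved = min(achieved, achieved_g) if ok else achieved_g
        converged &= ok
        n_iter_total = max(n_iter_total, it)

    weights = np.where(w > 0, w, np.nan)
    return BalanceResult(weights=weights, converged=converged,
                         achieved_tol=achieved, scope=scope, n_iter=n_iter_total)


# ---------------------------------------------------------------------------
# Expected and O/E
# ---------------------------------------------------------------------------

@dataclass
class ExpectedProfile:
    """Mean balanced contact per (chrom, diagonal offset), or per trans pair.

    ``cis[chrom]`` is an array indexed by offset in bins (NaN where no valid
    pixel exists); ``n_valid[chrom]`` the matching valid-pixel counts.
    """

    scope: str
    cis: dict = field(default_factory=dict)
    n_valid: dict = field(default_factory=dict)
    trans: dict = field(default_factory=dict)


def _valid_pairs_per_diagonal(valid: np.ndarray) -> np.ndarray:
    """n(d) = number of (i, i+d) pairs with both bins valid, via correlation."""
    m = valid.astype(np.float64)
    full = np.correlate(m, m, mode="full")
    return np.rint(full[len(m) - 1:]).astype(np.int64)


def compute_expected(matrix: ContactMatrix, scope: str = "cis") -> ExpectedProfile:
    """Distance-decay (cis) or scalar (trans) expected from a balanced matrix.

    Cis: for each chromosome and diagonal offset ``d``, the mean balanced
    value over all pixels whose two bins are both unmasked -- zero pixels
    (absent from storage) count toward the mean. Trans: one scalar per
    chromosome pair.
    """
    if matrix.weights is None:
        raise ValueError("matrix must be balanced before computing expected")
    if matrix.balancing_mode not in (scope, "total", "unit"):
        raise ValueError(
            f"balancing scope {matrix.balancing_mode!r} incompatible with expected scope {scope!r}")
    w = matrix.weights
    prof = ExpectedProfile(scope=scope)
    bins = matrix.bins
    if scope == "cis":
        for chrom in bins.chroms:
            s = bins.chrom_slices[chrom]
            block = matrix.upper[s, s].tocoo()
            wc = w[s.start:s.stop]
            valid = np.isfinite(wc)
            nb = s.stop - s.start
            b = block.data * np.nan_to_num(wc)[block.row] * np.nan_to_num(wc)[block.col]
            ok = valid[block.row] & valid[block.col]
            d = block.col - block.row
            sums = np.bincount(d[ok], weights=b[ok], minlength=nb)
            n_valid = _valid_pairs_per_diagonal(valid)
            with np.errstate(invalid="ignore", divide="ignore"):
                exp = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), np.nan)
            prof.cis[chrom] = exp
            prof.n_valid[chrom] = n_valid
    elif scope == "trans":
        for a_i, chrom_a in enumerate(bins.chroms):
            for chrom_b in bins.chroms[a_i + 1:]:
                sa, sb = bins.chrom_slices[chrom_a], bins.chrom_slices[chrom_b]
                block = matrix.upper[sa, sb].tocoo()
                wa, wb = w[sa], w[sb]
                va, vb = np.isfinite(wa), np.isfinite(wb)
                ok = va[block.row] & vb[block.col]
                total = float(np.sum(block.data[ok] * wa[block.row[ok]] * wb[block.col[ok]]))
                n_pix = int(va.sum()) * int(vb.sum())
                prof.trans[(chrom_a, chrom_b)] = total / n_pix if n_pix else np.nan
    else:
        raise ValueError(f"unknown expected scope {scope!r}")
    return prof


class OEMatrix:
    """Per-chromosome dense observed/expected values; NaN marks undefined.

    A pixel is defined when both bins are unmasked and expected at its offset
    is positive; stored-zero and absent pixels are 0.0 (a value, not missing).
    """

    def __init__(self, bins: BinTable, dense: dict[str, np.ndarray],
                 resolution: int, n_zero_expected: int = 0):
        self.bins = bins
        self.dense = dense
        self.resolution = resolution
        self.n_zero_expected = n_zero_expected  # pixels with observed>0 but expected 0

    def value(self, i: int, j: int) -> float:
        chrom = self.bins.chrom_of(i)
        if self.bins.chrom_of(j) != chrom:
            raise ValueError("cis O/E query across chromosomes")
        s = self.bins.chrom_slices[chrom]
        return float(self.dense[chrom][i - s.start, j - s.start])

    def values_at(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Vectorized pixel lookup for same-chromosome (global) index pairs."""
        out = np.full(len(i), np.nan)
        chrom_of = self.bins._chrom_of
        for chrom in self.bins.chroms:
            s = self.bins.chrom_slices[chrom]
            sel = (chrom_of[i] == chrom) & (chrom_of[j] == chrom)
            if sel.any():
                out[sel] = self.dense[chrom][i[sel] - s.start, j[sel] - s.start]
        return out


def observed_over_expected(matrix: ContactMatrix, expected: ExpectedProfile) -> OEMatrix:
    """Divide balanced observed by expected; undefined pixels become NaN.

    Undefined means: a masked bin on either side, or expected <= 0 at the
    pixel's offset. Pixels with observed > 0 but expected == 0 are tallied in
    the result's ``n_zero_expected`` diagnostic.
    """
    if matrix.weights is None:
        raise ValueError("matrix must be balanced")
    if expected.scope != "cis":
        raise ValueError("only cis O/E matrices are materialized")
    bins = matrix.bins
    dense: dict[str, np.ndarray] = {}
    n_zero_expected = 0
    for chrom in bins.chroms:
        s = bins.chrom_slices[chrom]
        wc = matrix.weights[s]
        valid = np.isfinite(wc)
        nb = len(wc)
        block = matrix.upper[s, s].toarray()
        balanced = block * np.nan_to_num(wc)[:, None] * np.nan_to_num(wc)[None, :]
        balanced = balanced + np.triu(balanced, 1).T  # symmetrize
        offs = np.abs(np.arange(nb)[None, :] - np.arange(nb)[:, None])
        exp = expected.cis[chrom][offs]
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = balanced / exp
        undef = ~valid[:, None] | ~valid[None, :] | ~(exp > 0)
        n_zero_expected += int(np.sum((balanced > 0) & ~(exp > 0)
                                      & valid[:, None] & valid[None, :]))
        oe[undef] = np.nan
        dense[chrom] = oe
    return OEMatrix(bins, dense, bins.resolution, n_zero_expected)
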