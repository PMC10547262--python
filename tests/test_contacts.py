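"""Contact-matrix core: loading, ICE balancing, expected, O/E.

The dense oracle used throughout recomputes expected and O/E by direct
pixel enumeration on small matrices, independent of the sparse code path.
"""

import numpy as np
import pandas as pd
import pytest

from ulitools.contacts import (
    BinTable, ContactMatrix, compute_expected, iterative_correction,
    load_contacts, observed_over_expected,
)
from conftest import random_matrix


# ---------------------------------------------------------------------------
# dense oracle
# ---------------------------------------------------------------------------

def dense_balanced(matrix):
    """Dense symmetric balanced matrix with NaN at masked bins."""
    n = matrix.bins.n_bins
    d = matrix.symmetric().toarray().astype(float)
    w = matrix.weights
    out = d * w[:, None] * w[None, :]
    return out


def oracle_expected_cis(matrix, chrom):
    """Brute-force per-diagonal mean over valid pixels (zeros included)."""
    s = matrix.bins.chrom_slices[chrom]
    b = dense_balanced(matrix)[s, s]
    valid = np.isfinite(matrix.weights[s])
    nb = b.shape[0]
    exp = np.full(nb, np.nan)
    for d in range(nb):
        vals = [b[i, i + d] for i in range(nb - d) if valid[i] and valid[i + d]]
        if vals:
            exp[d] = np.mean(vals)
    return exp


def oracle_oe(matrix, chrom):
    s = matrix.bins.chrom_slices[chrom]
    b = dense_balanced(matrix)[s, s]
    valid = np.isfinite(matrix.weights[s])
    exp = oracle_expected_cis(matrix, chrom)
    nb = b.shape[0]
    oe = np.full((nb, nb), np.nan)
    for i in range(nb):
        for j in range(nb):
            e = exp[abs(i - j)]
            if valid[i] and valid[j] and np.isfinite(e) and e > 0:
                oe[i, j] = b[i, j] / e
    return oe


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

class TestLoadContacts:
    def test_symmetric_query(self):
        bins = BinTable.from_chrom_lengths({"chr1": 30_000}, 10_000)
        m = load_contacts(bins, [(0, 0, 4), (0, 2, 1)])
        assert m.value(2, 0) == 1
        assert m.value(0, 2) == 1
        assert m.value(0, 0) == 4

    def test_lower_triangle_input_canonicalized_and_duplicates_summed(self):
        bins = BinTable.from_chrom_lengths({"chr1": 30_000}, 10_000)
        m = load_contacts(bins, [(2, 0, 1), (0, 2, 2)])
        assert m.value(0, 2) == 3
        assert m.upper[2, 0] == 0  # upper triangle storage only

    def test_empty_triplets(self):
        bins = BinTable.from_chrom_lengths({"chr1": 30_000}, 10_000)
        m = load_contacts(bins, [])
        assert m.total_count() == 0

    def test_out_of_range_index_names_row(self):
        bins = BinTable.from_chrom_lengths({"chr1": 30_000}, 10_000)
        with pytest.raises(ValueError, match="row 1.*99"):
            load_contacts(bins, [(0, 1, 2), (0, 99, 3)])

    def test_negative_count(self):
        bins = BinTable.from_chrom_lengths({"chr1": 30_000}, 10_000)
        with pytest.raises(ValueError, match="negative"):
            load_contacts(bins, [(0, 1, -2)])

    def test_count_mass_conserved(self, small_bins, rng):
        m = random_matrix(small_bins, rng)
        trip = m.upper.tocoo()
        assert m.total_count() == trip.data.sum()


class TestBinTable:
    def test_bin_assignment_floor(self, small_bins):
        assert small_bins.bin_of("chr1", 0) == 0
        assert small_bins.bin_of("chr1", 9_999) == 0
        assert small_bins.bin_of("chr1", 10_000) == 1

    def test_noncontiguous_rejected(self):
        df = pd.DataFrame({"chrom": ["chr1", "chr1"],
                           "start": [0, 20_000], "end": [10_000, 30_000]})
        with pytest.raises(ValueError, match="tile"):
            BinTable(df, 10_000)

    def test_last_bin_may_be_short(self):
        bt = BinTable.from_chrom_lengths({"chr1": 25_000}, 10_000)
        assert bt.n_bins == 3
        assert bt.df["end"].iloc[-1] == 25_000


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------

class TestIterativeCorrection:
    def test_equal_row_sums_gives_equal_weights(self):
        bins = BinTable.from_chrom_lengths({"chr1": 30_000}, 10_000)
        # constant off-diagonal matrix: all raw coverages equal
        m = load_contacts(bins, [(0, 1, 2), (0, 2, 2), (1, 2, 2)])
        res = iterative_correction(m, scope="total", tol=1e-10)
        w = res.weights
        assert res.converged
        assert np.allclose(w, w[0], rtol=1e-6)

    def test_rank_one_closed_form(self, rng):
        # counts v_i * v_j -> weights proportional to 1/v_i
        v = rng.uniform(0.5, 3.0, size=12)
        bins = BinTable.from_chrom_lengths({"chr1": 120_000}, 10_000)
        iu, ju = np.triu_indices(12)
        trip = pd.DataFrame({"bin1_id": iu, "bin2_id": ju,
                             "count": v[iu] * v[ju]})
        m = load_contacts(bins, trip)
        res = iterative_correction(m, scope="total", tol=1e-12, max_iter=2000,
                                   mad_filter=0)
        w = res.weights
        prod = w * v
        assert np.allclose(prod, prod[0], rtol=1e-6)
        # all balanced entries equal
        bal = dense_balanced(ContactMatrix(bins, m.upper, w))
        assert np.allclose(bal, bal[0, 0], rtol=1e-5)

    def test_two_bin_symmetric(self):
        bins = BinTable.from_chrom_lengths({"chr1": 20_000}, 10_000)
        m = load_contacts(bins, [(0, 1, 4)])
        m.balance(scope="cis", tol=1e-10)
        bal = dense_balanced(m)
        assert np.isclose(bal.sum(axis=1)[0], bal.sum(axis=1)[1])

    def test_idempotence_on_balanced_matrix(self, random_small_matrix):
        m = random_small_matrix
        m.balance(scope="total", tol=1e-12, max_iter=2000)
        bal = dense_balanced(m)
        bal[~np.isfinite(bal)] = 0.0
        iu, ju = np.triu_indices(m.bins.n_bins)
        m2 = load_contacts(m.bins, np.column_stack([iu, ju, bal[iu, ju]]))
        res2 = iterative_correction(m2, scope="total", tol=1e-9, mad_filter=0)
        w2 = res2.weights[np.isfinite(res2.weights)]
        assert np.allclose(w2, 1.0, atol=1e-4)

    def test_all_zero_errors(self, small_bins):
        m = load_contacts(small_bins, [])
        with pytest.raises(ValueError, match="no unmasked"):
            iterative_correction(m)

    def test_low_coverage_bin_masked(self, small_bins, rng):
        m = random_matrix(small_bins, rng, density=1.0, max_count=500)
        # bin 5: essentially no coverage compared to the others
        upper = m.upper.tolil()
        upper[5, :] = 0
        upper[:, 5] = 0
        upper[5, 6] = 1e-8
        m2 = ContactMatrix(m.bins, upper.tocsr())
        res = iterative_correction(m2, scope="total")
        assert not np.isfinite(res.weights[5])

    def test_cis_scope_balances_chromosomes_independently(self, two_chrom_bins, rng):
        m = random_matrix(two_chrom_bins, rng, density=1.0)
        res = iterative_correction(m, scope="cis", tol=1e-10, max_iter=1000)
        bal = m.symmetric().toarray() * np.nan_to_num(res.weights)[:, None] \
            * np.nan_to_num(res.weights)[None, :]
        for chrom in two_chrom_bins.chroms:
            s = two_chrom_bins.chrom_slices[chrom]
            cov = bal[s, s].sum(axis=1)
            cov = cov[np.isfinite(res.weights[s])]
            assert np.allclose(cov, 1.0, atol=1e-6)


# ---------------------------------------------------------------------------
# expected and O/E
# ---------------------------------------------------------------------------

class TestExpectedAndOE:
    def test_constant_diagonal(self):
        bins = BinTable.from_chrom_lengths({"chr1": 40_000}, 10_000)
        trip = [(i, i + 1, 5) for i in range(3)]
        m = load_contacts(bins, trip)
        m.weights = np.ones(4)
        m.balancing_mode = "total"
        exp = compute_expected(m, "cis")
        assert np.isclose(exp.cis["chr1"][1], 5.0)

    def test_all_zero_matrix_expected_zero(self, small_bins):
        m = load_contacts(small_bins, [(0, 1, 0)])
        m.weights = np.ones(small_bins.n_bins)
        m.balancing_mode = "total"
        exp = compute_expected(m, "cis")
        assert np.allclose(exp.cis["chr1"], 0.0)

    def test_masked_bins_match_bruteforce(self, random_small_matrix):
        m = random_small_matrix
        m.balance(scope="total")
        m.weights[[3, 7]] = np.nan  # mask two bins by hand
        exp = compute_expected(m, "cis")
        oracle = oracle_expected_cis(m, "chr1")
        np.testing.assert_allclose(exp.cis["chr1"], oracle, rtol=1e-12,
                                   equal_nan=True)

    def test_unbalanced_matrix_rejected(self, random_small_matrix):
        with pytest.raises(ValueError, match="balanced"):
            compute_expected(random_small_matrix, "cis")

    def test_oe_identity_and_ratio(self, random_small_matrix):
        m = random_small_matrix
        m.balance(scope="total")
        exp = compute_expected(m, "cis")
        oe = observed_over_expected(m, exp)
        # per-diagonal mean of defined O/E values = 1 (self-normalization)
        dense = oe.dense["chr1"].astype(np.float64)
        nb = dense.shape[0]
        for d in range(nb):
            diag = np.array([dense[i, i + d] for i in range(nb - d)])
            diag = diag[np.isfinite(diag)]
            if len(diag):
                assert abs(diag.mean() - 1.0) < 1e-6

    def test_oe_matches_dense_oracle(self, rng):
        bins = BinTable.from_chrom_lengths({"chr1": 300_000}, 10_000)  # 30 bins
        m = random_matrix(bins, rng, density=0.5)
        m.balance(scope="total")
        m.weights[rng.choice(30, size=4, replace=False)] = np.nan
        exp = compute_expected(m, "cis")
        oe = observed_over_expected(m, exp)
        oracle = oracle_oe(m, "chr1")
        np.testing.assert_allclose(oe.dense["chr1"].astype(np.float64), oracle,
                                   rtol=1e-5, equal_nan=True)

    def test_double_expected_halves_oe(self, random_small_matrix):
        m = random_small_matrix
        m.balance(scope="total")
        exp = compute_expected(m, "cis")
        oe1 = observed_over_expected(m, exp)
        exp.cis["chr1"] = exp.cis["chr1"] * 2.0
        oe2 = observed_over_expected(m, exp)
        with np.errstate(invalid="ignore"):
            ratio = oe2.dense["chr1"] / oe1.dense["chr1"]
        ok = np.isfinite(ratio) & (oe1.dense["chr1"] != 0)
        assert np.allclose(ratio[ok], 0.5, rtol=1e-5)

    def test_trans_expected_scalar(self, two_chrom_bins):
        trip = [(0, 20, 6), (1, 21, 2)]  # chr1 x chr2 pixels
        m = load_contacts(two_chrom_bins, trip)
        m.weights = np.ones(two_chrom_bins.n_bins)
        m.balancing_mode = "total"
        exp = compute_expected(m, "trans")
        n_pix = 20 * 10
        assert np.isclose(exp.trans[("chr1", "chr2")], 8.0 / n_pix)
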