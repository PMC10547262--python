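"""Contact screen: pair enumeration, central-pixel extraction, Mann-Whitney
effect size against brute-force oracles, and screen filtering rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ulitools.contacts import compute_expected, observed_over_expected
from ulitools.screen import (
    FactorDataset, STRATUM_LONG, STRATUM_SHORT, enumerate_pairs,
    extract_central_oe, mannwhitney_effect, one_side_screen, run_screen,
)
from conftest import random_matrix


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_u_f(bound, unbound):
    """U by direct enumeration of all pairwise comparisons (ties = 1/2)."""
    u = 0.0
    for x in bound:
        for y in unbound:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u, u / (len(bound) * len(unbound))


def brute_force_exact_p(bound, unbound):
    """Exact two-sided p: twice the smaller tail of the permutation
    distribution of U, by complete enumeration of group assignments."""
    pooled = list(bound) + list(unbound)
    n1 = len(bound)
    u_obs, _ = brute_force_u_f(bound, unbound)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        grp = [pooled[i] for i in comb]
        rest = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u, _ = brute_force_u_f(grp, rest)
        us.append(u)
    us = np.array(us)
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_spec_example(self):
        u, f, _ = mannwhitney_effect([1, 2, 3], [0, 0])
        assert u == 6 and f == 1.0

    def test_complete_ties_give_half(self):
        _, f, p = mannwhitney_effect([1, 1], [1, 1])
        assert f == 0.5
        assert p == 1.0

    def test_complement_symmetry(self, rng):
        bound = rng.integers(0, 5, size=7).astype(float)
        unbound = rng.integers(0, 5, size=5).astype(float)
        _, f, _ = mannwhitney_effect(bound, unbound)
        _, f_swapped, _ = mannwhitney_effect(unbound, bound)
        assert np.isclose(f + f_swapped, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mannwhitney_effect([], [1.0])

    def test_oracle_agreement_small_samples(self, rng):
        """U and F exactly match enumeration; p matches exact enumeration."""
        for _ in range(60):
            n1 = int(rng.integers(1, 9))
            n2 = int(rng.integers(1, 9))
            # integer values force plenty of ties
            bound = rng.integers(0, 4, size=n1).astype(float)
            unbound = rng.integers(0, 4, size=n2).astype(float)
            u, f, p = mannwhitney_effect(bound, unbound)
            u_ref, f_ref = brute_force_u_f(bound, unbound)
            assert u == u_ref
            assert f == f_ref
            p_ref = brute_force_exact_p(bound, unbound)
            assert abs(p - p_ref) < 1e-9

    def test_large_sample_p_matches_scipy(self, rng):
        """Asymptotic branch agrees with the reference implementation's
        tie-corrected normal approximation with continuity correction."""
        bound = rng.normal(0.3, 1.0, size=80)
        unbound = rng.normal(0.0, 1.0, size=90)
        u, _, p = mannwhitney_effect(bound, unbound)
        ref = stats.mannwhitneyu(bound, unbound, alternative="two-sided",
                                 method="asymptotic")
        assert np.isclose(u, ref.statistic)
        assert np.isclose(p, ref.pvalue, rtol=1e-10)


# ---------------------------------------------------------------------------
# pair enumeration and extraction
# ---------------------------------------------------------------------------

def cres_at(chrom_mids, halfwidth=500):
    rows = [(c, m - halfwidth, m + halfwidth) for c, m in chrom_mids]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestEnumeratePairs:
    def test_stratum_assignment(self):
        cres = cres_at([("chr1", 1_000_000), ("chr1", 1_150_000),
                        ("chr1", 6_150_000), ("chr1", 1_050_000)])
        pairs = enumerate_pairs(cres)
        seps = dict(zip(zip(pairs["mid_a"], pairs["mid_b"]), pairs["stratum"]))
        assert seps[(1_000_000, 1_150_000)] == STRATUM_SHORT   # 150 kb
        assert seps[(1_150_000, 6_150_000)] == STRATUM_LONG    # 5 Mb
        assert (1_000_000, 1_050_000) not in seps              # 50 kb excluded

    def test_bounds_half_open(self):
        cres = cres_at([("chr1", 0), ("chr1", 10_000_000)])
        assert len(enumerate_pairs(cres)) == 0  # exactly max_sep: excluded
        cres = cres_at([("chr1", 1_000), ("chr1", 101_000)])
        assert len(enumerate_pairs(cres)) == 1  # exactly min_sep: included

    def test_genome_order(self):
        cres = cres_at([("chr1", 5_000_000), ("chr1", 1_000_000)])
        pairs = enumerate_pairs(cres)
        assert (pairs["mid_a"] < pairs["mid_b"]).all()


class TestExtractCentralOE:
    def make_oe(self, rng, length=400_000):
        from ulitools.contacts import BinTable
        bins = BinTable.from_chrom_lengths({"chr1": length}, 10_000)
        m = random_matrix(bins, rng, density=0.8)
        m.balance(scope="total")
        exp = compute_expected(m, "cis")
        return observed_over_expected(m, exp)

    def test_matches_pixel_lookup(self, rng):
        oe = self.make_oe(rng)
        cres = cres_at([("chr1", 15_000), ("chr1", 135_000)])
        pairs = enumerate_pairs(cres, min_sep=100_000, max_sep=400_000,
                                breaks=(100_000, 400_000))
        got = extract_central_oe(pairs, oe)
        assert np.isclose(got["oe_value"].iloc[0], oe.value(1, 13), equal_nan=True)

    def test_masked_bin_gives_missing(self, rng):
        oe = self.make_oe(rng)
        oe.dense["chr1"][13, :] = np.nan
        oe.dense["chr1"][:, 13] = np.nan
        cres = cres_at([("chr1", 15_000), ("chr1", 135_000)])
        pairs = enumerate_pairs(cres, min_sep=100_000, max_sep=400_000,
                                breaks=(100_000, 400_000))
        got = extract_central_oe(pairs, oe)
        assert np.isnan(got["oe_value"].iloc[0])


# ---------------------------------------------------------------------------
# screen driver
# ---------------------------------------------------------------------------

def synthetic_pairs(rng, n_cres=60, chrom="chr1"):
    mids = np.sort(rng.choice(np.arange(200, 3000), size=n_cres, replace=False)) * 10_000
    cres = cres_at([(chrom, int(m)) for m in mids])
    pairs = enumerate_pairs(cres)
    pairs["oe_value"] = rng.lognormal(0.0, 0.5, size=len(pairs))
    return cres, pairs


class TestRunScreen:
    def test_min_regions_filter(self, rng):
        cres, pairs = synthetic_pairs(rng)
        flags = {"tiny": np.zeros(len(cres), dtype=bool)}
        flags["tiny"][:3] = True
        ds = [FactorDataset("tiny", "tiny", pd.DataFrame(columns=["chrom", "start", "end"]))]
        res, skips = run_screen(pairs, cres, ds, min_regions=500, flags=flags)
        assert len(res) == 0
        assert "overlaps 3 CREs < 500" in skips["reason"].iloc[0]

    def test_min_group_filter_and_padj(self, rng):
        cres, pairs = synthetic_pairs(rng)
        flags = {"f": rng.random(len(cres)) < 0.5}
        ds = [FactorDataset("f", "f", None)]
        res, skips = run_screen(pairs, cres, ds, min_regions=1, min_group=50,
                                flags=flags)
        for row in res.itertuples():
            assert row.n_bound >= 50 and row.n_unbound >= 50
            assert np.isclose(row.p_adj, min(1.0, row.p * len(res)))
            assert row.p_adj >= row.p

    def test_order_invariance(self, rng):
        cres, pairs = synthetic_pairs(rng)
        flags = {"a": rng.random(len(cres)) < 0.5, "b": rng.random(len(cres)) < 0.6}
        ds = [FactorDataset("a", "a", None), FactorDataset("b", "b", None)]
        res1, _ = run_screen(pairs, cres, ds, min_regions=1, min_group=5, flags=flags)
        res2, _ = run_screen(pairs, cres, ds[::-1], min_regions=1, min_group=5,
                             flags=flags)
        merged = res1.merge(res2, on=["dataset", "stratum"], suffixes=("_1", "_2"))
        assert np.allclose(merged["F_1"], merged["F_2"])
        assert np.allclose(merged["p_adj_1"], merged["p_adj_2"])

    def test_missing_oe_dropped(self, rng):
        cres, pairs = synthetic_pairs(rng)
        pairs.loc[pairs.index[:10], "oe_value"] = np.nan
        fl = rng.random(len(cres)) < 0.5
        ds = [FactorDataset("f", "f", None)]
        res, _ = run_screen(pairs, cres, ds, min_regions=1, min_group=5,
                            flags={"f": fl})
        defined = pairs[np.isfinite(pairs["oe_value"])]
        for row in res.itertuples():
            in_s = defined[defined["stratum"] == row.stratum]
            a, b = in_s["a"].to_numpy(), in_s["b"].to_numpy()
            assert row.n_bound == int((fl[a] & fl[b]).sum())
            assert row.n_unbound == int((~fl[a] & ~fl[b]).sum())


class TestOneSideScreen:
    def test_group_membership(self, rng):
        cres, pairs = synthetic_pairs(rng, n_cres=80)
        n = len(cres)
        factor = rng.random(n) < 0.4
        other_tf = rng.random(n) < 0.5
        any_tf = factor | other_tf
        res = one_side_screen(pairs, factor, any_tf, min_group=5)
        assert set(res["comparison"]) <= {"both", "one_side"}
        # baseline + groups are disjoint by construction: factor-one-side pairs
        # with a bare other side are in neither group
        a, b = pairs["a"].to_numpy(), pairs["b"].to_numpy()
        lonely = factor[a] & ~any_tf[b]
        baseline = ~any_tf[a] & ~any_tf[b]
        both = factor[a] & factor[b]
        one_side = (factor[a] & ~factor[b] & any_tf[b]) | (factor[b] & ~factor[a] & any_tf[a])
        assert not np.any(lonely & (both | one_side | baseline))
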