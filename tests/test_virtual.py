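"""Virtual Hi-C / pileup / FISH observables on hand-built trajectories."""

import numpy as np
import pytest

from ulitools.polymer import BindingSiteMap, PolymerConfig, Trajectory
from ulitools.virtual import (
    VirtualContactMap, site_bead_contact_enrichment, site_enrichment,
    virtual_fish, virtual_hic, virtual_pileup,
)


def make_traj(frames, n_beads, site_indices=(), site_types=(), n_binders=0,
              **cfg_kw):
    """Trajectory from explicit frame arrays (chromatin first)."""
    cfg_kw.setdefault("n_steps", 1000)
    cfg_kw.setdefault("sample_every", 100)
    cfg_kw.setdefault("density", 0.001)
    cfg = PolymerConfig(n_beads=n_beads, n_site_beads=len(site_indices),
                        n_types=max(list(site_types) + [1]),
                        n_binders=n_binders, **cfg_kw)
    frames = np.asarray(frames, dtype=float)
    sm = BindingSiteMap(indices=np.array(site_indices, dtype=np.int64),
                        types=np.array(site_types, dtype=np.int64))
    return Trajectory(frames=frames, times=np.arange(len(frames), dtype=float),
                      on_states=np.ones((len(frames), n_binders), dtype=np.uint8),
                      config=cfg, site_map=sm)


def straight_chain(n_beads, spacing=1.0):
    pos = np.zeros((n_beads, 3))
    pos[:, 0] = np.arange(n_beads) * spacing
    return pos


class TestVirtualHiC:
    def test_contact_threshold_in_nm(self):
        # beads 30 nm apart (1 sigma): contact; beads 100 nm apart: none
        chain = straight_chain(3, spacing=100 / 30)  # 100 nm spacing
        chain[1] = chain[0] + [1.0, 0, 0]            # bead1 at 30 nm from bead0
        traj = make_traj([chain], n_beads=3, bp_per_bead=3000)
        vmap = virtual_hic(traj, threshold_nm=90.0, bin_beads=1)
        assert vmap.counts[0, 1] == 1    # 30 nm < 90 nm
        assert vmap.counts[0, 2] == 0    # > 90 nm apart
        assert vmap.counts[1, 2] == 0    # 70+ nm? (100-30): within 90 -> check
        # bead1 at x=1.0 sigma, bead2 at x=6.67 sigma: 5.67 sigma = 170 nm
        assert vmap.counts.dtype == np.int64

    def test_binning_by_seven_beads(self):
        # beads 0 and 6 share a bin; 0 and 7 are in adjacent bins
        spread = straight_chain(10, spacing=50.0)  # nothing else in contact
        pos = spread.copy()
        pos[6] = pos[0] + [1.0, 0, 0]
        traj = make_traj([pos], n_beads=10)
        vmap = virtual_hic(traj, bin_beads=7)
        assert vmap.counts[0, 0] == 1
        pos2 = spread.copy()
        pos2[7] = pos2[0] + [1.0, 0, 0]
        vmap2 = virtual_hic(make_traj([pos2], n_beads=10), bin_beads=7)
        assert vmap2.counts[0, 1] == 1 and vmap2.counts[0, 0] == 0

    def test_counts_accumulate_over_frames(self):
        chain = straight_chain(4)
        traj = make_traj([chain, chain, chain], n_beads=4)
        vmap = virtual_hic(traj, bin_beads=1)
        assert vmap.counts[0, 1] == 3
        assert vmap.n_frames == 3

    def test_rigid_motion_invariance(self, rng):
        frames = rng.uniform(0, 5, size=(3, 20, 3))
        traj = make_traj(frames, n_beads=20)
        vmap = virtual_hic(traj, bin_beads=2)
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        moved = frames @ q.T + np.array([10.0, -4.0, 2.0])
        vmap2 = virtual_hic(make_traj(moved, n_beads=20), bin_beads=2)
        assert np.array_equal(vmap.counts, vmap2.counts)

    def test_symmetry(self, rng):
        frames = rng.uniform(0, 4, size=(2, 30, 3))
        vmap = virtual_hic(make_traj(frames, n_beads=30), bin_beads=3)
        assert np.array_equal(vmap.counts, vmap.counts.T)


class TestVirtualPileup:
    def test_zero_frames_zero_grid(self):
        traj = make_traj(np.empty((0, 50, 3)), n_beads=50,
                         site_indices=[10, 40], site_types=[1, 1])
        grid, n = virtual_pileup(traj, flank_beads=3, min_sep_beads=10)
        assert grid.shape == (7, 7)
        assert grid.sum() == 0 and n == 1

    def test_bridged_pair_counts_per_frame(self):
        n_beads = 60
        chain = straight_chain(n_beads, spacing=5.0)  # 150 nm spacing: no contacts
        a, b = 10, 50
        chain[b] = chain[a] + [1.0, 0, 0]  # permanently bridged at 30 nm < 54 nm
        frames = [chain] * 4
        traj = make_traj(frames, n_beads=n_beads, site_indices=[a, b],
                         site_types=[1, 2])
        grid, n = virtual_pileup(traj, flank_beads=3, min_sep_beads=10)
        assert n == 1
        assert grid[3, 3] == 4          # one count per frame at the center
        assert grid.sum() == 4          # flanks are 150 nm apart: nothing else

    def test_counts_are_nonnegative_integers(self, rng):
        frames = rng.uniform(0, 3, size=(2, 40, 3))
        traj = make_traj(frames, n_beads=40, site_indices=[8, 30],
                         site_types=[1, 1])
        grid, _ = virtual_pileup(traj, flank_beads=2, min_sep_beads=5)
        assert np.issubdtype(grid.dtype, np.integer)
        assert (grid >= 0).all()


class TestVirtualFISH:
    def test_window_is_17_beads(self):
        assert round(51.0 * 1000 / 3000) == 17

    def test_coincident_windows_colocalize(self):
        n_beads = 100
        chain = straight_chain(n_beads, spacing=10.0)
        a, b = 30, 70
        # fold the b-window exactly onto the a-window
        chain[b - 8: b + 9] = chain[a - 8: a + 9]
        traj = make_traj([chain], n_beads=n_beads, site_indices=[a, b],
                         site_types=[1, 1])
        res = virtual_fish(traj, np.array([[a, b]]))
        assert res.distances_nm[0, 0] == pytest.approx(0.0)
        assert res.colocalization_fraction[0] == 1.0
        assert res.separations_bp[0] == (b - a) * 3000

    def test_threshold_200nm(self):
        n_beads = 60
        chain = straight_chain(n_beads, spacing=0.0)
        chain[:, 0] = 0.0
        a, b = 20, 40
        chain[b - 8: b + 9] = chain[a - 8: a + 9] + [7.0, 0, 0]  # 210 nm apart
        traj = make_traj([chain], n_beads=n_beads, site_indices=[a, b],
                         site_types=[1, 1])
        res = virtual_fish(traj, np.array([[a, b]]))
        assert res.distances_nm[0, 0] == pytest.approx(210.0)
        assert res.colocalization_fraction[0] == 0.0

    def test_pairs_near_chain_end_skipped(self):
        chain = straight_chain(40)
        traj = make_traj([chain], n_beads=40, site_indices=[2, 30],
                         site_types=[1, 1])
        with pytest.raises(ValueError, match="no site pair"):
            virtual_fish(traj, np.array([[2, 30]]))  # window off the left end


class TestSiteEnrichment:
    def test_hand_built_map(self):
        """5-bin map with counts only between the two site bins."""
        counts = np.zeros((5, 5), dtype=np.int64)
        counts[0, 3] = counts[3, 0] = 10   # site-site pair, sep 3
        counts[1, 4] = counts[4, 1] = 2    # background pair, sep 3
        vmap = VirtualContactMap(counts=counts, bin_beads=1, bp_per_bead=3000,
                                 n_frames=1)
        sm = BindingSiteMap(indices=np.array([0, 3]), types=np.array([1, 1]))
        out = site_enrichment(vmap, sm, min_sep_bp=9000, n_beads=5)
        # homotypic: 10 observed vs background mean 2 at sep 3 -> ratio 5
        assert out["homotypic"] == pytest.approx(5.0)
        assert np.isnan(out["heterotypic"])  # no heterotypic pairs exist
        assert out["n_homotypic_pairs"] == 1

    def test_homotypic_heterotypic_split(self):
        counts = np.ones((8, 8), dtype=np.int64)
        vmap = VirtualContactMap(counts=counts, bin_beads=1, bp_per_bead=3000,
                                 n_frames=1)
        sm = BindingSiteMap(indices=np.array([0, 4, 7]),
                            types=np.array([1, 1, 2]))
        out = site_enrichment(vmap, sm, min_sep_bp=6000, n_beads=8)
        assert out["n_homotypic_pairs"] == 1     # (0,4)
        assert out["n_heterotypic_pairs"] == 2   # (0,7), (4,7)
        # uniform map: every ratio is exactly 1
        assert out["homotypic"] == pytest.approx(1.0)
        assert out["heterotypic"] == pytest.approx(1.0)

    def test_contact_probability_decays_on_control_chain(self):
        """Virtual Hi-C contact frequency from a non-interacting control run
        decreases with genomic separation (after smoothing), as expected for
        a confined ideal chain."""
        from ulitools.polymer import scaled_config, run_simulation
        from scipy.stats import spearmanr

        cfg = scaled_config(eps_specific=0.0, eps_nonspecific=0.0,
                            n_steps=30_000, sample_every=2_000)
        traj = run_simulation(cfg, seed=8).second_half()
        vmap = virtual_hic(traj, bin_beads=1)
        n = vmap.n_bins
        # mean contact frequency in log-spaced separation bins (>= 5 bins);
        # raw per-separation values plateau at zero far out, which would
        # drown a rank statistic in ties
        edges = np.unique(np.geomspace(1, n - 1, 9).astype(int))
        means = [np.mean([np.mean(np.diag(vmap.counts, d))
                          for d in range(lo, hi)])
                 for lo, hi in zip(edges[:-1], edges[1:])]
        rho, _ = spearmanr(np.arange(len(means)), means)
        assert len(means) >= 5
        assert rho < -0.8
        assert means[0] > means[-1]

    def test_bead_level_enrichment_on_uniform_contacts(self):
        # straight dense chain: every adjacent-ish pair in contact; site pairs
        # beyond min_sep never in contact -> enrichment undefined-from-zero
        chain = straight_chain(300, spacing=1.0)
        traj = make_traj([chain], n_beads=300,
                         site_indices=[50, 200], site_types=[1, 1])
        out = site_bead_contact_enrichment(traj, min_sep_beads=100)
        assert out["site_contacts"] == 0
        assert out["n_site_pairs"] == 1
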