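import numpy as np
import pandas as pd
import pytest

from ulitools.contacts import BinTable, load_contacts


@pytest.fixture
def rng():
    return np.random.default_rng(20230801)


@pytest.fixture
def small_bins():
    """One 200-kb chromosome at 10-kb resolution (20 bins)."""
    return BinTable.from_chrom_lengths({"chr1": 200_000}, 10_000)


@pytest.fixture
def two_chrom_bins():
    return BinTable.from_chrom_lengths({"chr1": 200_000, "chr2": 100_000}, 10_000)


def random_matrix(bins, rng, density=0.6, max_count=20):
    """Random symmetric count matrix over a bin table (upper-triplet input)."""
    n = bins.n_bins
    iu, ju = np.triu_indices(n)
    keep = rng.random(len(iu)) < density
    counts = rng.integers(1, max_count, size=keep.sum())
    trip = pd.DataFrame({"bin1_id": iu[keep], "bin2_id": ju[keep], "count": counts})
    return load_contacts(bins, trip)


@pytest.fixture
def random_small_matrix(small_bins, rng):
    return random_matrix(small_bins, rng)
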