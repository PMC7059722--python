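import numpy as np
import pandas as pd
import pytest

from capture3c.genome import Genome, GenomicInterval
from capture3c.pets import BaitRegion
from capture3c.simulate import SimConfig, simulate_pets


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_genome():
    return Genome({"chr1": 1_000_000, "chr2": 800_000})


@pytest.fixture
def two_baits(small_genome):
    return [
        BaitRegion("baitA", GenomicInterval("chr1", 100_000, 105_000, name="baitA")),
        BaitRegion("baitB", GenomicInterval("chr1", 400_000, 404_000, name="baitB")),
    ]


def small_sim_config(seed=5, **kw):
    """A desk-scale simulation: 8 baits on 2 x 2 Mb, ~4k bait PETs."""
    defaults = dict(
        seed=seed,
        chrom_lengths={"c1": 2_000_000, "c2": 2_000_000},
        n_baits=8,
        bait_margin=600_000,
        n_contacts=200_000,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_world():
    """Shared small simulated dataset with planted loops."""
    cfg = small_sim_config(seed=5, n_loops=5, loop_dist_range=(50_000, 400_000))
    pairs, truth, baits = simulate_pets(cfg)
    return cfg, pairs, truth, baits


def contacts_without_self_ligations(pairs: pd.DataFrame, baits) -> pd.DataFrame:
    from capture3c.pets import _BaitIndex

    idx = _BaitIndex(baits)
    b1 = idx.assign(pairs["chrom1"].to_numpy(dtype=object), pairs["pos1"].to_numpy())
    b2 = idx.assign(pairs["chrom2"].to_numpy(dtype=object), pairs["pos2"].to_numpy())
    return pairs.loc[~((b1 >= 0) & (b1 == b2))].reset_index(drop=True)
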