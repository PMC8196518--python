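import numpy as np
import pytest

from paircomp.genome import Genome
from paircomp.pipeline import run_compare
from paircomp.simulate import SimulationConfig, derive_cultivar, simulate_ancestor


def random_genome(rng, length, name="c1", gc=0.46):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return Genome({name: seq})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale cultivar pair: 2 x 150 kb with every event type."""
    return SimulationConfig(
        n_chromosomes=2, chrom_length=150_000, seed=5,
        n_pav_insertions=3, n_pav_deletions=3,
        pav_min_length=800, pav_max_length=4_000,
        n_inversions=2, inversion_length_range=(3_000, 8_000),
        n_intra_translocations=1, n_inter_translocations=1,
        translocation_length_range=(5_000, 10_000),
        enriched_block_length=50_000, enriched_grid=25_000)


@pytest.fixture(scope="session")
def small_pair(small_cfg):
    A = simulate_ancestor(small_cfg)
    B, truth = derive_cultivar(A, small_cfg, seed=6)
    return A, B, truth


@pytest.fixture(scope="session")
def small_result(small_pair):
    A, B, _ = small_pair
    return run_compare(A, B)


@pytest.fixture(scope="session")
def nosv_cfg():
    """No structural events: pure point-mutation divergence."""
    return SimulationConfig(
        n_chromosomes=1, chrom_length=1_000_000, seed=9,
        snp_rate_background=0.002, enriched_fraction=0.0, indel_rate=0.0004,
        n_pav_insertions=0, n_pav_deletions=0, n_inversions=0,
        n_intra_translocations=0, n_inter_translocations=0)


@pytest.fixture(scope="session")
def nosv_pair(nosv_cfg):
    A = simulate_ancestor(nosv_cfg)
    B, truth = derive_cultivar(A, nosv_cfg, seed=10)
    return A, B, truth
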