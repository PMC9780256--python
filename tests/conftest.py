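import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from patmut.kmer_counting import KmerCountTable
from patmut.iupac import pattern_match_mask
from patmut.simulate import example_truth, simulate_genome, simulate_mutations


def random_snv_table(seed: int, k: int = 3, central: str = "C",
                     alt: str = "T") -> KmerCountTable:
    """A random count table on the central-`central` k-mer space."""
    rng = np.random.default_rng(seed)
    h = k // 2
    root = "N" * h + central + "N" * (k - h - 1)
    t = KmerCountTable(k, f"{central}>{alt}")
    space = pattern_match_mask(root, k)
    t.m[space] = rng.integers(0, 40, int(space.sum()))
    t.u[space] = rng.integers(50, 5000, int(space.sum()))
    return t


def random_indel_table(seed: int, k: int = 2, label: str = "INS") -> KmerCountTable:
    rng = np.random.default_rng(seed)
    t = KmerCountTable(k, label)
    t.m[:] = rng.integers(0, 40, 4 ** k)
    t.u[:] = rng.integers(50, 5000, 4 ** k)
    return t


@pytest.fixture(scope="session")
def sim_data():
    """A 200 kb synthetic genome with mutations from the example truth."""
    genome, mask = simulate_genome(200_000, seed=11)
    truth = example_truth()
    muts = simulate_mutations(genome, mask, truth, seed=12)
    return genome, mask, truth, muts


@pytest.fixture(scope="session")
def snv_tables(sim_data):
    from patmut.kmer_counting import count_snv_kmers

    genome, mask, _truth, muts = sim_data
    return count_snv_kmers(muts, genome, mask, 3)
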