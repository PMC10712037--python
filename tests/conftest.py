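import pytest

from nucleocut import simulate


@pytest.fixture(scope="session")
def genome_small():
    """200-kb single-chromosome genome for fast unit tests."""
    return simulate.make_genome(1, 200_000, 0.41, seed=11)


@pytest.fixture(scope="session")
def genome_2mb():
    """2-Mb genome at the canonical study scale."""
    return simulate.make_genome(1, 2_000_000, 0.41, seed=5)


@pytest.fixture(scope="session")
def s1_fragments_small(genome_small):
    """Size-selected S1 digestion of the small genome (2 cells)."""
    frags = simulate.digest(genome_small, simulate.s1(1000), n_cells=2, seed=21)
    return simulate.size_select(frags, 1000)
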