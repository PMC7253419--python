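import numpy as np
import pytest

from chromdyn.genome_io import BinGrid, GenomeIndex, Interval


@pytest.fixture
def small_genome():
    return GenomeIndex({"chr1": 10_000, "chr2": 4_000})


@pytest.fixture
def small_grid(small_genome):
    return BinGrid(small_genome, 200)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_intervals(rng, genome, n, max_len=500):
    """Uniform random intervals over a genome (test helper)."""
    out = []
    names = list(genome.names)
    for i in range(n):
        chrom = names[int(rng.integers(len(names)))]
        L = genome.lengths[chrom]
        start = int(rng.integers(0, L - 1))
        end = min(L, start + 1 + int(rng.integers(max_len)))
        out.append(Interval(chrom, start, end, name=f"iv{i}",
                            score=float(rng.integers(100)),
                            strand="+" if rng.random() < 0.5 else "-"))
    return out
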