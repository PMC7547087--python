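import numpy as np
import pytest

from ervdyn.genome import GenomeModel, GenomicInterval, IntervalSet
from ervdyn.simulate import SimulationConfig, simulate_genome_and_annotation


@pytest.fixture
def toy_genome():
    return GenomeModel({"chr1": 10_000, "chr2": 8_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_interval_set(rng, genome, n, max_len=2000, named=True):
    """Random intervals on a genome, for oracle-comparison tests."""
    ivs = []
    chroms = genome.chromosomes
    for i in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        length = int(rng.integers(1, min(max_len, genome.lengths[chrom] - 1)))
        start = int(rng.integers(0, genome.lengths[chrom] - length))
        ivs.append(
            GenomicInterval(chrom, start, start + length, f"iv{i}" if named else ".")
        )
    return IntervalSet(ivs)


def paint(intervals, length, chrom=None):
    """Per-base coverage counts by brute-force painting (test oracle)."""
    vec = np.zeros(length)
    for iv in intervals:
        if chrom is None or iv.chrom == chrom:
            vec[iv.start:iv.end] += 1
    return vec


# small, quick simulation shared by unit tests (module-independent seed)
SMALL_SIM = dict(
    seed=5,
    chrom_lengths=(200_000, 150_000),
    n_full_elements=5,
    n_solo_ltrs=3,
    n_other_repeats=2,
    n_enhancers=4,
    n_tss=4,
    depth_x=10.0,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(**SMALL_SIM)


@pytest.fixture(scope="session")
def small_ann(small_cfg):
    return simulate_genome_and_annotation(small_cfg)
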