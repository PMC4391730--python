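import numpy as np
import pytest

from xallele import synthetic
from xallele.genes import GeneModel
from xallele.snps import SnpTable


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SimConfig(
        genome_length=20_000, n_chromosomes=2, snp_rate=1 / 75, read_length=100,
        coverage=5.0, seed=11,
    )


@pytest.fixture(scope="session")
def genome_pair(small_config):
    return synthetic.simulate_genome_pair(small_config)


@pytest.fixture(scope="session")
def sim_reads(small_config, genome_pair):
    reference, snps = genome_pair
    return synthetic.simulate_reads(
        reference, snps, small_config, region_skew={"chrX": 0.16}
    )


@pytest.fixture(scope="session")
def alignments(small_config, genome_pair, sim_reads):
    reference, _ = genome_pair
    reads, _ = sim_reads
    header = synthetic.alignment_header({c: len(s) for c, s in reference.items()})
    return synthetic.reads_to_alignments(reads, header)


@pytest.fixture
def toy_genes():
    return [
        GeneModel("gx_plus", "chrX", "+", 10_000, ((10_000, 13_000),), "X", "subject"),
        GeneModel("gx_minus", "chrX", "-", 30_000, ((27_001, 30_001),), "X", "subject"),
        GeneModel("ga", "chr1", "+", 10_000, ((10_000, 13_000),), "autosome", "unknown"),
    ]
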