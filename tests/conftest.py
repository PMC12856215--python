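import numpy as np
import pytest

from spliceclip.intervals import GeneModel, GenomicInterval, build_feature_space
from spliceclip.simulate import SimulationConfig, simulate_genome


def random_intervals(rng, n, chrom="chr1", chrom_len=10_000, max_len=500, stranded=True):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, chrom_len - 1))
        length = int(rng.integers(1, max_len + 1))
        end = min(chrom_len, start + length)
        strand = rng.choice(["+", "-"]) if stranded else "."
        out.append(GenomicInterval(chrom, start, end, str(strand)))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_exon_gene():
    exons = (
        GenomicInterval("chr1", 100, 200, "+"),
        GenomicInterval("chr1", 300, 400, "+"),
    )
    return GeneModel("geneA", "chr1", "+", exons)


@pytest.fixture
def toy_genome():
    """Small simulated genome shared by the slower integration tests."""
    cfg = SimulationConfig(
        n_chrom=1,
        chrom_length=500_000,
        n_genes=40,
        n_events={"SE": 30, "RI": 10, "MXE": 5, "A5SS": 5, "A3SS": 5},
        n_sites=100,
    )
    sizes, genes = simulate_genome(cfg, np.random.default_rng(7))
    return cfg, sizes, genes, build_feature_space(genes)
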