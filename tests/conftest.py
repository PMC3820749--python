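import numpy as np
import pytest

from ashkit.intervals import GeneModel, Genome, GenomicInterval, Peak, PeakSet
from ashkit.synth import SyntheticConfig, draw_labels, place_genes


@pytest.fixture
def small_genome():
    return Genome({"chr1": 100_000, "chr2": 80_000})


@pytest.fixture
def small_world():
    """A compact but fully structured synthetic world (200 genes)."""
    cfg = SyntheticConfig(seed=11, n_genes=200, n_chroms=2)
    genome, genes = place_genes(cfg)
    truth = draw_labels(cfg, genes)
    return cfg, genome, genes, truth


def random_gene(rng: np.random.Generator, genome: Genome, gene_id: str) -> GeneModel:
    chrom = str(rng.choice(list(genome.chrom_sizes)))
    size = genome.chrom_sizes[chrom]
    length = int(rng.integers(200, size // 4))
    start = int(rng.integers(0, size - length))
    strand = str(rng.choice(["+", "-"]))
    return GeneModel(gene_id, GenomicInterval(chrom, start, start + length), strand)


def random_peaks(rng: np.random.Generator, genome: Genome, n: int, factor="X") -> PeakSet:
    peaks = []
    for i in range(n):
        chrom = str(rng.choice(list(genome.chrom_sizes)))
        size = genome.chrom_sizes[chrom]
        width = int(rng.integers(50, 2000))
        start = int(rng.integers(0, size - width))
        peaks.append(Peak(GenomicInterval(chrom, start, start + width), name=f"p{i}"))
    return PeakSet(factor, peaks)
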