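import dataclasses

import numpy as np
import pandas as pd
import pytest

from ectoseq import SimulationConfig, simulate_dataset
from ectoseq.models import GeneModel


#: Reduced-size study design used where a test only needs the dataset's
#: structure (paralog pair, overlap pair, junctions), not its depth.
SMALL_CONFIG = SimulationConfig(
    genome_size=1_000_000,
    n_chromosomes=2,
    n_marker_genes=8,
    n_or_genes=8,
    n_other_genes=10,
    library_size=100_000,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size simulated dataset (three samples, 1e6 fragments
    each, intergenic noise 0.5/kb) shared across read-only tests."""
    return simulate_dataset(seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(SMALL_CONFIG, seed=5)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Full-size dataset without intergenic noise and without the
    unannotated overlapping transcript (pure gene-derived fragments)."""
    cfg = dataclasses.replace(
        SimulationConfig(), intergenic_noise_rate=0.0, overlap_apparent_fpkm=0.0
    )
    return simulate_dataset(cfg, seed=29)


def single_exon_gene(
    gene_id="G1",
    chromosome="chr1",
    start=100,
    length=1000,
    strand="+",
    family="other",
):
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_id,
        chromosome=chromosome,
        strand=strand,
        transcripts=[[(start, start + length)]],
        family=family,
        cds=(start, start + length),
    )


def random_instance(rng, max_genes=10, max_fragments=50, chrom_names=("chr1", "chr2")):
    """Random small counting instance: genes may overlap each other and
    fragments may be split; used for oracle-equivalence checks."""
    from ectoseq.models import fragments_frame

    n_genes = int(rng.integers(1, max_genes + 1))
    genes = []
    for i in range(n_genes):
        chrom = str(rng.choice(chrom_names))
        start = int(rng.integers(0, 5000))
        n_ex = int(rng.integers(1, 4))
        exons, pos = [], start
        for _ in range(n_ex):
            length = int(rng.integers(50, 400))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(20, 300))
        genes.append(
            GeneModel(f"g{i}", f"g{i}", chrom, "+", [exons], family="other")
        )
    n_frags = int(rng.integers(0, max_fragments + 1))
    blocks, chroms, uniq = [], [], []
    for _ in range(n_frags):
        chrom = str(rng.choice(chrom_names))
        s = int(rng.integers(0, 6000))
        if rng.random() < 0.3:
            l1 = int(rng.integers(20, 120))
            gap = int(rng.integers(10, 400))
            l2 = int(rng.integers(20, 120))
            blocks.append([(s, s + l1), (s + l1 + gap, s + l1 + gap + l2)])
        else:
            blocks.append([(s, s + int(rng.integers(40, 300)))])
        chroms.append(chrom)
        uniq.append(bool(rng.random() < 0.9))
    frags = fragments_frame("s1", chroms, blocks, uniq) if n_frags else None
    return genes, frags
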