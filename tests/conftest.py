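"""Shared fixtures: toy genomes, gene models, and seeded rngs."""

from __future__ import annotations

import numpy as np
import pytest

from epimark.core import GeneModel, GenomicInterval, ReadAlignment, ReadSet


def make_gene(gene_id, chrom, start, end, strand, exon_pairs=None):
    if exon_pairs is None:
        exon_pairs = [(start, end)]
    return GeneModel(
        gene_id=gene_id,
        span=GenomicInterval(chrom, start, end, strand),
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs),
    )


def make_reads(positions, chrom="chr1", strand="+", length=49):
    return ReadSet.from_records(
        [ReadAlignment(chrom, int(p), strand, length) for p in positions]
    )


def random_toy_genome(rng, n_genes=10, chrom_len=100_000, n_chroms=1, flank=5_000):
    """Random small gene models for brute-force oracle comparisons.

    Genes may overlap each other's flanks (that is the point of the oracle
    tests); spans never leave the chromosome.
    """
    genes = []
    sizes = {f"chr{c + 1}": chrom_len for c in range(n_chroms)}
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        length = int(rng.integers(200, chrom_len // 4))
        start = int(rng.integers(0, chrom_len - length))
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 4))
        if n_ex == 1 or length < 2 * n_ex:
            exons = [(start, start + length)]
        else:
            cuts = sorted(rng.choice(np.arange(1, length), size=2 * n_ex - 2, replace=False))
            bounds = [0] + [int(c) for c in cuts] + [length]
            exons = [
                (start + bounds[2 * e], start + bounds[2 * e + 1]) for e in range(n_ex)
            ]
        genes.append(make_gene(f"t{i}", chrom, start, start + length, strand, exons))
    return genes, sizes


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_gene():
    # one '+' gene, single exon covering the span
    return make_gene("g1", "chr1", 30_000, 40_000, "+")
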