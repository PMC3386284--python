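"""Profile geometometries: offset arithmetic, conservation, mirroring, dip recovery."""

import numpy as np
import pytest

from epimark.core import GeneModel, GenomicInterval
from epimark.profiles import (
    aggregate_density,
    metagene_profile,
    promoter_window_densities,
    tss_profile_matrix,
)
from epimark.simulate import SimulationConfig, simulate_chip_reads, simulate_expression, simulate_gene_models

from conftest import make_gene, make_reads, random_toy_genome


def brute_force_tss_counts(genes, positions, window, span):
    ncol = 2 * span // window
    out = np.zeros((len(genes), ncol), dtype=int)
    for i, g in enumerate(genes):
        for p in positions:
            off = g.oriented_offset(int(p))
            if -span <= off < span:
                out[i, (off + span) // window] += 1
    return out


class TestTssGeometry:
    def test_plus_strand_offset_column(self):
        g = make_gene("g", "chr1", 10_000, 15_000, "+")
        m = tss_profile_matrix(make_reads([7_990]), [g], window=50, span=20_000)
        col = np.flatnonzero(m.counts[0])[0]
        assert m.col_offsets[col] == -2_050  # [-2050, -2000) contains -2010

    def test_minus_strand_mirroring(self):
        g = make_gene("g", "chr1", 5_000, 10_001, "-")  # tss = 10_000
        m = tss_profile_matrix(make_reads([12_010]), [g], window=50, span=20_000)
        col = np.flatnonzero(m.counts[0])[0]
        assert m.col_offsets[col] == -2_050

    def test_matches_brute_force(self, rng):
        genes, _ = random_toy_genome(rng, n_genes=3, chrom_len=60_000)
        positions = rng.integers(0, 60_000, size=20)
        m = tss_profile_matrix(make_reads(positions), genes, window=500, span=10_000)
        assert np.array_equal(m.counts, brute_force_tss_counts(genes, positions, 500, 10_000))

    def test_conservation(self, rng):
        genes, _ = random_toy_genome(rng, n_genes=5, chrom_len=60_000)
        positions = rng.integers(0, 60_000, size=500)
        m = tss_profile_matrix(make_reads(positions), genes, window=100, span=5_000)
        oracle = brute_force_tss_counts(genes, positions, 100, 5_000)
        assert m.counts.sum() == oracle.sum()

    def test_out_of_range_columns_masked(self):
        g = make_gene("g", "chr1", 1_000, 3_000, "+")
        m = tss_profile_matrix(
            make_reads([]), [g], window=500, span=5_000, genome_sizes={"chr1": 5_000}
        )
        assert not m.valid[0, 0]  # would start at -4000 absolute
        assert m.valid[0, m.col_offsets.tolist().index(0)]
        assert not m.valid[0, -1]  # beyond the 5 kb chromosome


class TestStrandMirrorInvariance:
    def test_reversing_genome_preserves_profiles(self, rng):
        L = 50_000
        genes, _ = random_toy_genome(rng, n_genes=4, chrom_len=L)
        positions = rng.integers(0, L, size=300)
        m = tss_profile_matrix(make_reads(positions), genes, window=250, span=5_000)
        flip = lambda x: L - 1 - x
        rgenes = [
            GeneModel(
                g.gene_id,
                GenomicInterval(g.chrom, flip(g.span.end - 1), flip(g.span.start) + 1,
                                "-" if g.strand == "+" else "+"),
                tuple(
                    GenomicInterval(e.chrom, flip(e.end - 1), flip(e.start) + 1,
                                    "-" if g.strand == "+" else "+")
                    for e in reversed(g.exons)
                ),
            )
            for g in genes
        ]
        rm = tss_profile_matrix(make_reads([flip(p) for p in positions]), rgenes,
                                window=250, span=5_000)
        assert np.array_equal(m.counts, rm.counts)


class TestMetagene:
    def test_body_bin_assignment(self):
        g = make_gene("g", "chr1", 100_000, 102_000, "+")
        # read at 43% of the body -> bin floor(0.43 * 20) = 8 (0-indexed)
        m = metagene_profile(make_reads([100_860]), [g])
        col = np.flatnonzero(m.counts[0])[0]
        assert col == 20 + 8
        assert m.bp[0, 20:40] == pytest.approx(100.0)

    def test_uniform_reads_give_flat_densities(self, rng):
        g = make_gene("g", "chr1", 100_000, 120_000, "+")
        lam = 0.05  # 50 reads per kb >> 10 per bin
        n = rng.poisson(lam * 60_000)
        reads = make_reads(rng.integers(80_000, 140_000, size=n))
        m = metagene_profile(reads, [g])
        dens = m.densities()[0]
        assert np.std(dens) / np.mean(dens) < 0.15

    def test_matches_brute_force(self, rng):
        genes, _ = random_toy_genome(rng, n_genes=4, chrom_len=60_000)
        genes = [g for g in genes if g.length >= 20]
        positions = rng.integers(0, 60_000, size=200)
        m = metagene_profile(reads := make_reads(positions), genes, flank_kb=2)
        expect = np.zeros_like(m.counts)
        for i, g in enumerate(genes):
            L = g.length
            for p in positions:
                off = g.oriented_offset(int(p))
                if -2_000 <= off < 0:
                    expect[i, (off + 2_000) // 1000] += 1
                elif 0 <= off < L:
                    expect[i, 2 + min(off * 20 // L, 19)] += 1
                elif L <= off < L + 2_000:
                    expect[i, 22 + (off - L) // 1000] += 1
        assert np.array_equal(m.counts, expect)

    def test_short_genes_excluded(self):
        short = make_gene("s", "chr1", 1_000, 1_010, "+")
        ok = make_gene("ok", "chr1", 50_000, 60_000, "+")
        m = metagene_profile(make_reads([]), [short, ok])
        assert m.gene_ids == ["ok"]


class TestPromoterWindows:
    def test_edge_convention_left_closed(self):
        g = make_gene("g", "chr1", 10_000, 15_000, "+")
        m = promoter_window_densities(make_reads([8_500]), [g])  # offset -1500
        assert np.flatnonzero(m.counts[0])[0] == 7  # [-1500, -1000)

    def test_no_upstream_reads_gives_zero_row(self):
        g = make_gene("g", "chr1", 10_000, 15_000, "+")
        m = promoter_window_densities(make_reads([12_000]), [g])
        assert m.counts[0].sum() == 0

    def test_equals_rebinned_tss_matrix(self, rng):
        genes, _ = random_toy_genome(rng, n_genes=5, chrom_len=60_000)
        reads = make_reads(rng.integers(0, 60_000, size=800))
        prom = promoter_window_densities(reads, genes)
        tss = tss_profile_matrix(reads, genes, window=50, span=5_000)
        upstream = tss.counts[:, :100]  # [-5000, 0) as 100 x 50 bp
        rebinned = upstream.reshape(len(genes), 10, 10).sum(axis=2)
        assert np.array_equal(prom.counts, rebinned)


class TestAggregateDensity:
    def test_mean_density_arithmetic(self):
        g1 = make_gene("a", "chr1", 10_000, 15_000, "+")
        g2 = make_gene("b", "chr1", 40_000, 45_000, "+")
        reads = make_reads([9_990] * 4 + [39_990] * 6)  # 4 and 6 in [-50, 0)
        m = tss_profile_matrix(reads, [g1, g2], window=50, span=100)
        col = m.col_offsets.tolist().index(-50)
        assert aggregate_density(m)[col] == pytest.approx((4 + 6) / (2 * 50))

    def test_single_gene_identity(self):
        g = make_gene("a", "chr1", 10_000, 15_000, "+")
        m = tss_profile_matrix(make_reads([9_000, 9_001]), [g], window=500, span=2_000)
        assert np.allclose(aggregate_density(m, ["a"]), m.densities()[0])

    def test_empty_gene_set_is_error(self):
        g = make_gene("a", "chr1", 10_000, 15_000, "+")
        m = tss_profile_matrix(make_reads([]), [g])
        with pytest.raises(ValueError):
            aggregate_density(m, [])


class TestPlantedDipRecovery:
    def test_all_gene_aggregate_minimum_at_tss_column(self):
        # planted nucleosome-depletion dip: the aggregate curve over all
        # genes must bottom out in the TSS-containing 50 bp column
        cfg = SimulationConfig(
            seed=42, n_genes=400, n_chroms=1, chrom_length_bp=24_000_000,
            depth_reads=1_500_000,
        )
        genes, sizes = simulate_gene_models(cfg)
        expr = simulate_expression(genes, cfg)
        reads, _ = simulate_chip_reads(genes, expr.truth_tpm, cfg, sizes)
        m = tss_profile_matrix(reads, genes, window=50, span=1_000, genome_sizes=sizes)
        curve = aggregate_density(m)
        sel = (m.col_offsets >= -500) & (m.col_offsets < 500)
        assert m.col_offsets[sel][np.nanargmin(curve[sel])] == 0

    def test_dip_ablation_removes_the_dip(self):
        cfg = SimulationConfig(
            seed=42, n_genes=200, n_chroms=1, chrom_length_bp=12_000_000,
            depth_reads=800_000, tss_dip_depth=0.0,
        )
        genes, sizes = simulate_gene_models(cfg)
        expr = simulate_expression(genes, cfg)
        reads, _ = simulate_chip_reads(genes, expr.truth_tpm, cfg, sizes)
        m = tss_profile_matrix(reads, genes, window=100, span=500, genome_sizes=sizes)
        curve = aggregate_density(m)
        # without the dip the TSS column is no longer a clear minimum:
        # upstream columns are higher (broad term) but the TSS column is
        # comparable to its downstream neighbours
        tss_col = m.col_offsets.tolist().index(0)
        assert curve[tss_col] > 0.5 * curve[tss_col + 1]
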