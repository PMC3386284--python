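"""Synthetic-data generator: determinism, constraints, ablations, parseability."""

import numpy as np
import pytest

from epimark import io as eio
from epimark.annotation import build_region_partition
from epimark.distribution import assign_reads_to_regions
from epimark.dge import tpm_normalize
from epimark.simulate import (
    SimulationConfig,
    repression_coupling,
    simulate_chip_reads,
    simulate_expression,
    simulate_gene_models,
    simulate_peaks,
    simulate_two_group_study,
)

SMALL = dict(n_genes=40, n_chroms=2, chrom_length_bp=1_200_000,
             depth_reads=40_000, depth_tags=50_000, n_affected=10)


class TestGeneModels:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=7, **SMALL)
        g1, s1 = simulate_gene_models(cfg)
        g2, s2 = simulate_gene_models(cfg)
        assert s1 == s2
        assert [(g.gene_id, g.span, g.exons) for g in g1] == [
            (g.gene_id, g.span, g.exons) for g in g2
        ]

    def test_flanks_do_not_overlap(self):
        cfg = SimulationConfig(seed=3, **SMALL)
        genes, _ = simulate_gene_models(cfg)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for glist in by_chrom.values():
            glist.sort(key=lambda g: g.span.start)
            for a, b in zip(glist, glist[1:]):
                assert a.span.end + cfg.flank <= b.span.start - cfg.flank + 1

    def test_strand_alternation_balanced(self):
        genes, _ = simulate_gene_models(SimulationConfig(seed=1, **SMALL))
        plus = sum(1 for g in genes if g.strand == "+")
        assert abs(plus - (len(genes) - plus)) <= 1

    def test_infeasible_packing_names_required_size(self):
        cfg = SimulationConfig(seed=0, n_genes=100, n_chroms=1, chrom_length_bp=1_000_000)
        with pytest.raises(ValueError, match="need >="):
            simulate_gene_models(cfg)


class TestExpression:
    def test_exact_silent_fraction_and_tpm_sum(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        genes, _ = simulate_gene_models(cfg)
        expr = simulate_expression(genes, cfg)
        assert len(expr.silent_genes) == round(0.3 * len(genes))
        assert sum(expr.truth_tpm.values()) == pytest.approx(1e6)
        assert all(expr.truth_tpm[g] == 0.0 for g in expr.silent_genes)

    def test_estimate_error_shrinks_with_depth(self):
        cfg_lo = SimulationConfig(seed=9, **{**SMALL, "depth_tags": 20_000})
        cfg_hi = SimulationConfig(seed=9, **{**SMALL, "depth_tags": 500_000})
        genes, _ = simulate_gene_models(cfg_lo)

        def mean_abs_rel_err(cfg):
            expr = simulate_expression(genes, cfg)
            est = tpm_normalize(expr.sample_counts[0], expr.sample_totals[0])
            errs = [
                abs(est.get(g, 0.0) - t) / t
                for g, t in expr.truth_tpm.items()
                if t > 1_000  # genes with enough signal at both depths
            ]
            return np.mean(errs)

        assert mean_abs_rel_err(cfg_hi) < mean_abs_rel_err(cfg_lo)

    def test_coupling_is_descending_rank_fraction(self):
        r = repression_coupling({"a": 100.0, "b": 10.0, "c": 0.0})
        assert r == {"a": 0.0, "b": 0.5, "c": 1.0}


class TestChipReads:
    def test_no_enrichment_ablation_uniform_abundance(self):
        cfg = SimulationConfig(
            seed=4, bump_amplitude=0.0, broad_amplitude=0.0, tss_dip_depth=0.0,
            **{**SMALL, "depth_reads": 200_000},
        )
        genes, sizes = simulate_gene_models(cfg)
        expr = simulate_expression(genes, cfg)
        reads, _ = simulate_chip_reads(genes, expr.truth_tpm, cfg, sizes)
        summary = assign_reads_to_regions(reads, build_region_partition(genes, sizes))
        for lab, ab in summary.abundance.items():
            assert ab == pytest.approx(1.0, abs=0.1), lab

    def test_reads_parse_and_round_trip_through_bed(self, tmp_path):
        cfg = SimulationConfig(seed=6, **SMALL)
        genes, sizes = simulate_gene_models(cfg)
        expr = simulate_expression(genes, cfg)
        reads, _ = simulate_chip_reads(genes, expr.truth_tpm, cfg, sizes)
        p = tmp_path / "reads.bed"
        eio.write_bed_reads(p, reads)
        again = eio.read_bed_reads(p)
        assert again.n_rejected == 0
        assert len(again) == len(reads)
        assert np.array_equal(np.sort(again.pos5), np.sort(reads.pos5))

    def test_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(seed=8, **SMALL)
        genes, sizes = simulate_gene_models(cfg)
        expr = simulate_expression(genes, cfg)
        out = []
        for name in ("a.bed", "b.bed"):
            reads, _ = simulate_chip_reads(genes, expr.truth_tpm, cfg, sizes)
            p = tmp_path / name
            eio.write_bed_reads(p, reads)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_truth_table_carries_coupling(self):
        cfg = SimulationConfig(seed=2, **SMALL)
        genes, sizes = simulate_gene_models(cfg)
        expr = simulate_expression(genes, cfg)
        _, truth = simulate_chip_reads(genes, expr.truth_tpm, cfg, sizes)
        assert set(truth.columns) >= {"gene_id", "r", "tss", "strand", "tpm"}
        # silent genes carry the largest coupling values
        silent_r = truth.set_index("gene_id").loc[expr.silent_genes, "r"]
        assert silent_r.min() > truth["r"].median()


class TestTwoGroup:
    def test_affected_band_and_renormalization(self):
        cfg = SimulationConfig(seed=12, **SMALL)
        study = simulate_two_group_study(cfg, chip=False)
        assert len(study.affected_genes) == cfg.n_affected
        assert sum(study.truth_tpm_b.values()) == pytest.approx(1e6)
        affected = set(study.affected_genes)
        unaffected = [g for g, t in study.truth_tpm_a.items() if t > 0 and g not in affected]
        base = study.truth_tpm_a[unaffected[0]] / study.truth_tpm_b[unaffected[0]]
        # TPM renormalization rescales everything by one global factor, so
        # affected genes sit exactly 2^delta = 4-fold below the others
        for g in study.affected_genes:
            ratio = study.truth_tpm_a[g] / study.truth_tpm_b[g]
            assert ratio == pytest.approx(4.0 * base, rel=1e-9)

    def test_too_many_affected_rejected(self):
        cfg = SimulationConfig(seed=12, **{**SMALL, "n_affected": 1_000})
        with pytest.raises(ValueError, match="n_affected"):
            simulate_two_group_study(cfg, chip=False)

    def test_samples_differ_but_groups_share_truth(self):
        cfg = SimulationConfig(seed=13, **SMALL)
        study = simulate_two_group_study(cfg, chip=False)
        assert study.tag_counts["A"][0] != study.tag_counts["A"][1]
        assert study.tag_totals["A"][0] == cfg.depth_tags


class TestSimulatedPeaks:
    def test_peaks_sit_on_most_repressed_promoters(self):
        cfg = SimulationConfig(seed=14, **SMALL)
        genes, sizes = simulate_gene_models(cfg)
        expr = simulate_expression(genes, cfg)
        peaks = simulate_peaks(genes, expr.truth_tpm, cfg, top_fraction=0.2)
        assert len(peaks) == round(0.2 * len(genes))
        r = repression_coupling(expr.truth_tpm)
        covered = {p.name.removeprefix("peak_") for p in peaks}
        uncovered_max = max(v for g, v in r.items() if g not in covered)
        covered_min = min(r[g] for g in covered)
        assert covered_min >= uncovered_max - 1e-12
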