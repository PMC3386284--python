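"""End-to-end orchestration: config in, plain-text stage outputs + manifest out.

A run executes, in order: simulate (optional) -> annotate -> distribution ->
profiles -> peak association -> DGE/DE -> integration -> window comparison.
Every inter-stage artifact is a TSV/BED/JSON file under the output
directory; stages communicate only through those files' in-memory
equivalents, and a manifest records sha256 digests of every input and
output, so a rerun with the same config and seed is byte-identical.

Config is YAML.  Either a ``simulation`` block (keys are
:class:`~epimark.simulate.SimulationConfig` fields) or an ``inputs`` block
naming ``genes``, ``chrom_sizes``, ``reads`` (one BED per sample per group)
and optionally ``peaks`` and ``tags`` must be present; missing inputs fail
fast before any stage runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .annotation import build_region_partition, region_genome_fractions
from .core import ReadSet
from .dge import (
    differential_expression,
    pick_strata,
    stratify_by_expression,
    tpm_normalize,
)
from .diffmod import compare_promoter_windows
from .distribution import assign_reads_to_regions
from .integration import classify_concordance, spearman_centroid_cluster, stratified_profiles
from .peaks import associate_peaks_with_genes, peak_region_percentages, peak_summary_stats
from .profiles import promoter_window_densities
from .simulate import SimulationConfig, simulate_peaks, simulate_two_group_study

__all__ = ["RunManifest", "run_full_analysis"]


@dataclass
class RunManifest:
    config_hash: str
    input_digests: dict[str, str]
    output_digests: dict[str, str]
    warnings: dict[str, int]
    outputs: list[str]
    version: str = "0.1.0"

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config_hash": self.config_hash,
                "inputs": self.input_digests,
                "outputs": {k: self.output_digests[k] for k in sorted(self.output_digests)},
                "warnings": {k: self.warnings[k] for k in sorted(self.warnings)},
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(path: Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _mean_group_density(read_sets: list[ReadSet], genes, gene_ids, genome_sizes) -> np.ndarray:
    """Per-gene promoter densities, RPM-scaled and averaged over samples."""
    sub = [g for g in genes if g.gene_id in set(gene_ids)]
    mats = [
        promoter_window_densities(r, sub, genome_sizes=genome_sizes) for r in read_sets
    ]
    stack = np.stack([m.densities(rpm=True) for m in mats])
    return np.nanmean(stack, axis=0)


def run_full_analysis(config, outdir) -> RunManifest:
    """Run the full pipeline; see the module docstring for the stage order."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()
    warnings: dict[str, int] = {}
    input_digests: dict[str, str] = {}
    outputs: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        outputs.append(path)
        return path

    # ---------------------------------------------------------------- inputs
    if "simulation" in cfg:
        sim_kwargs = dict(cfg["simulation"] or {})
        if "seed" in cfg and "seed" not in sim_kwargs:
            sim_kwargs["seed"] = int(cfg["seed"])
        if "gene_length_range" in sim_kwargs:
            sim_kwargs["gene_length_range"] = tuple(sim_kwargs["gene_length_range"])
        sim_cfg = SimulationConfig(**sim_kwargs)
        study = simulate_two_group_study(sim_cfg)
        genes, chrom_sizes = study.genes, study.chrom_sizes
        reads_by_group = study.reads
        tag_counts, tag_totals = study.tag_counts, study.tag_totals
        peaks = simulate_peaks(genes, study.truth_tpm_a, sim_cfg)
        emit("genes.tsv", lambda p: eio.write_gene_table(p, genes))
        emit("chrom.sizes", lambda p: eio.write_chrom_sizes(p, chrom_sizes))
        for grp in ("A", "B"):
            for i, rd in enumerate(reads_by_group[grp], start=1):
                emit(f"reads_{grp}{i}.bed", lambda p, rd=rd: eio.write_bed_reads(p, rd))
            for i, counts in enumerate(tag_counts[grp], start=1):
                emit(f"tags_{grp}{i}.tsv", lambda p, c=counts: eio.write_tag_counts(p, c))
        emit("peaks.xls", lambda p: eio.write_macs_peaks(p, peaks))
        emit(
            "truth_affected.tsv",
            lambda p: _write_tsv(p, pd.DataFrame({"gene_id": study.affected_genes})),
        )
        affected = study.affected_genes
    else:
        inputs = cfg.get("inputs")
        if not inputs:
            raise ValueError("config needs a 'simulation' or 'inputs' block")
        missing = [
            k for k in ("genes", "chrom_sizes", "reads") if k not in inputs
        ]
        for k, v in list(inputs.items()):
            paths = v if isinstance(v, (list, dict)) else [v]
            flat = paths.values() if isinstance(paths, dict) else paths
            for item in flat:
                for pth in item if isinstance(item, list) else [item]:
                    if not Path(pth).exists():
                        missing.append(f"{k}:{pth}")
        if missing:
            raise ValueError(f"missing inputs: {', '.join(map(str, missing))}")
        genes = eio.read_gene_table(inputs["genes"])
        chrom_sizes = eio.read_chrom_sizes(inputs["chrom_sizes"])
        rd_cfg = inputs["reads"]
        if isinstance(rd_cfg, dict):
            reads_by_group = {
                grp: [eio.read_bed_reads(p) for p in paths] for grp, paths in rd_cfg.items()
            }
        else:
            reads_by_group = {"A": [eio.read_bed_reads(p) for p in rd_cfg]}
        for k, v in inputs.items():
            flat = v.values() if isinstance(v, dict) else ([v] if isinstance(v, str) else v)
            for item in flat:
                for pth in item if isinstance(item, list) else [item]:
                    input_digests[str(pth)] = _sha256(Path(pth))
        peaks = eio.read_macs_peaks(inputs["peaks"]) if "peaks" in inputs else []
        if "tags" in inputs:
            tag_counts, tag_totals = {}, {}
            for grp, paths in inputs["tags"].items():
                tables = [eio.read_tag_counts(p) for p in paths]
                tag_counts[grp] = [dict(zip(t["gene_id"], t["count"])) for t in tables]
                tag_totals[grp] = [int(t["count"].sum()) for t in tables]
        else:
            tag_counts = tag_totals = None
        affected = None

    flank = int(cfg.get("flank", 20_000))
    seed = int(cfg.get("seed", 0))
    reads_main = reads_by_group["A"][0]

    # -------------------------------------------------------------- annotate
    index_ml = build_region_partition(genes, chrom_sizes, flank=flank, mode="multilabel")
    index_ex = build_region_partition(genes, chrom_sizes, flank=flank, mode="exclusive")
    fractions = pd.DataFrame(
        {
            "label": list(region_genome_fractions(index_ml)),
            "multilabel_fraction": list(region_genome_fractions(index_ml).values()),
            "exclusive_fraction": [
                region_genome_fractions(index_ex)[k] for k in region_genome_fractions(index_ml)
            ],
        }
    )
    emit("genome_fractions.tsv", lambda p: _write_tsv(p, fractions))

    # ---------------------------------------------------------- distribution
    summary = assign_reads_to_regions(reads_main, index_ml)
    emit("read_distribution.tsv", lambda p: _write_tsv(p, summary.to_frame()))
    warnings["reads_on_unknown_chrom"] = summary.n_unknown_chrom

    # ------------------------------------------------------------------- dge
    report_rows: list[tuple[str, float]] = []
    if tag_counts is not None and "B" in tag_counts:
        pooled_a = {}
        for counts in tag_counts["A"]:
            for g, c in counts.items():
                pooled_a[g] = pooled_a.get(g, 0) + c
        pooled_b = {}
        for counts in tag_counts["B"]:
            for g, c in counts.items():
                pooled_b[g] = pooled_b.get(g, 0) + c
        total_a, total_b = sum(pooled_a.values()), sum(pooled_b.values())
        tpm = tpm_normalize(pooled_a, total_a)
        for g in genes:
            tpm.setdefault(g.gene_id, 0.0)
        de = differential_expression(pooled_a, total_a, pooled_b, total_b)
        de_frame = pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in de],
                "count_a": [r.count_a for r in de],
                "count_b": [r.count_b for r in de],
                "log2_ratio": [r.log2_ratio for r in de],
                "p_value": [r.p_value for r in de],
                "fdr": [r.fdr for r in de],
                "significant": [r.significant for r in de],
            }
        )
        emit("de.tsv", lambda p: _write_tsv(p, de_frame))
        emit(
            "tpm.tsv",
            lambda p: eio.write_tag_counts(p, pooled_a, tpm),
        )
        n_de = int(de_frame["significant"].sum())
        n_down = int((de_frame["significant"] & (de_frame["log2_ratio"] > 0)).sum())
        report_rows += [("n_de_genes", n_de), ("n_de_down_in_B", n_down)]
        de_down = [r.gene_id for r in de if r.significant and r.log2_ratio > 0]
    else:
        pooled_a = {}
        for counts in tag_counts["A"] if tag_counts else []:
            for g, c in counts.items():
                pooled_a[g] = pooled_a.get(g, 0) + c
        tpm = tpm_normalize(pooled_a, sum(pooled_a.values())) if pooled_a else {}
        for g in genes:
            tpm.setdefault(g.gene_id, 0.0)
        de_down = []

    # -------------------------------------------------------------- profiles
    sets = stratify_by_expression(tpm, n_sets=10)
    strata = pick_strata(sets)
    offsets, curves = stratified_profiles(
        reads_main, genes, strata, geometry="tss", genome_sizes=chrom_sizes
    )
    prof = pd.DataFrame({"offset": offsets, **{k: curves[k] for k in sorted(curves)}})
    emit("profiles_tss.tsv", lambda p: _write_tsv(p, prof))
    labels_mg, curves_mg = stratified_profiles(
        reads_main, genes, strata, geometry="metagene", genome_sizes=chrom_sizes
    )
    prof_mg = pd.DataFrame({"bin": labels_mg, **{k: curves_mg[k] for k in sorted(curves_mg)}})
    emit("profiles_metagene.tsv", lambda p: _write_tsv(p, prof_mg))

    # ----------------------------------------------------------------- peaks
    if peaks:
        assoc = associate_peaks_with_genes(peaks, genes, flank=flank, genome_sizes=chrom_sizes)
        assoc_frame = pd.DataFrame(
            {
                "gene_id": [a.gene_id for a in assoc],
                "labels": [",".join(sorted(a.labels)) for a in assoc],
                "n_peaks": [len(a.peak_ids) for a in assoc],
            }
        )
        emit("peak_associations.tsv", lambda p: _write_tsv(p, assoc_frame))
        stats = peak_summary_stats(peaks)
        pct = peak_region_percentages(assoc) if assoc else {}
        report_rows += [
            ("n_peaks", stats["n"]),
            ("peak_mean_length_bp", stats["mean_length_bp"]),
            ("n_genes_with_peaks", len(assoc)),
        ] + [(f"peak_pct_{k}", v) for k, v in sorted(pct.items())]

    # ------------------------------------------------------------ integration
    prom = promoter_window_densities(reads_main, genes, genome_sizes=chrom_sizes)
    prom_mean = {
        g: float(np.nanmean(d)) for g, d in zip(prom.gene_ids, prom.densities())
    }
    calls = classify_concordance(tpm, prom_mean)
    call_frame = pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "expression_class": [c.expression_class for c in calls],
            "mark_class": [c.mark_class for c in calls],
            "call": [c.call for c in calls],
        }
    )
    emit("concordance.tsv", lambda p: _write_tsv(p, call_frame))
    discordant = [c for c in calls if c.call in ("co_expressed", "co_suppressed")]
    report_rows.append(
        ("discordant_fraction", len(discordant) / len(calls) if calls else float("nan"))
    )
    # small feature matrix for the cluster stage: expression + promoter mark
    cluster_genes = sorted(tpm, key=lambda g: -tpm[g])[:40]
    feat = pd.DataFrame(
        {
            "log_tpm": [np.log1p(tpm[g]) for g in cluster_genes],
            "promoter_density": [prom_mean.get(g, 0.0) for g in cluster_genes],
            "rank": [float(i) for i in range(len(cluster_genes))],
        },
        index=cluster_genes,
    )
    feat = feat.loc[feat.apply(np.ptp, axis=1) > 0]
    if len(feat) >= 2:
        cl = spearman_centroid_cluster(feat)
        emit(
            "cluster_leaves.tsv",
            lambda p: _write_tsv(p, pd.DataFrame({"leaf_order": cl.leaf_order})),
        )

    # --------------------------------------------------------------- compare
    gene_set = affected if affected else de_down
    if gene_set and "B" in reads_by_group and len(gene_set) >= 3:
        dens_a = _mean_group_density(reads_by_group["A"], genes, gene_set, chrom_sizes)
        dens_b = _mean_group_density(reads_by_group["B"], genes, gene_set, chrom_sizes)
        results = compare_promoter_windows(dens_a, dens_b)
        win_frame = pd.DataFrame(
            {
                "window_start": [r.window[0] for r in results],
                "window_end": [r.window[1] for r in results],
                "mean_density_A": [r.mean_density_a for r in results],
                "mean_density_B": [r.mean_density_b for r in results],
                "t": [r.t_statistic for r in results],
                "p": [r.p_value for r in results],
                "flagged": [r.flagged for r in results],
            }
        )
        emit("window_comparison.tsv", lambda p: _write_tsv(p, win_frame))
        report_rows.append(
            ("flagged_windows", ";".join(str(r.window[0]) for r in results if r.flagged))
        )

    # ---------------------------------------------------------------- report
    for lab in ("up20K", "exon", "intron", "down20K", "intergenic"):
        report_rows.append((f"read_pct_{lab}", summary.read_pct.get(lab, 0.0)))
        report_rows.append((f"abundance_{lab}", summary.abundance.get(lab, float("nan"))))
    report_rows.append(("n_reads", len(reads_main)))
    report_rows.append(("seed", seed))
    report = pd.DataFrame(report_rows, columns=["metric", "value"])
    emit("report.tsv", lambda p: _write_tsv(p, report))

    output_digests = {p.name: _sha256(p) for p in outputs}
    manifest = RunManifest(
        config_hash=config_hash,
        input_digests=input_digests,
        output_digests=output_digests,
        warnings=warnings,
        outputs=[p.name for p in outputs],
    )
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
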