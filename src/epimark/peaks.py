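"""Peak-gene association, peak summaries, and saturation curves.

A peak is associated with a gene as soon as it shares >= 1 bp with any of
the gene's four region classes (up20K, exon, intron, down20K); a gene
appears once with the union of the region labels through which it is hit.
Because the labels are not exclusive, per-label percentages of associated
genes can sum past 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import intervals as iv
from .annotation import GENIC_LABELS, gene_region_intervals
from .core import GeneModel, Peak, ReadSet

__all__ = [
    "PeakGeneAssociation",
    "associate_peaks_with_genes",
    "peak_region_percentages",
    "peak_summary_stats",
    "saturation_curve",
]


@dataclass
class PeakGeneAssociation:
    gene_id: str
    labels: frozenset[str]
    peak_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("association without region labels")


def associate_peaks_with_genes(
    peaks: list[Peak],
    genes: list[GeneModel],
    flank: int = 20_000,
    genome_sizes: dict[str, int] | None = None,
) -> list[PeakGeneAssociation]:
    """All (gene, labels, peaks) associations under the >= 1 bp overlap rule.

    Uses a per-chromosome sorted sweep over gene-region intervals; the
    result is invariant to the order of either input list (output is sorted
    by gene_id).
    """
    # region table per chromosome: arrays of start, end, gene index, label index
    by_chrom: dict[str, list[tuple[int, int, int, int]]] = {}
    for gi, g in enumerate(genes):
        chrom_len = genome_sizes.get(g.chrom) if genome_sizes else None
        regions = gene_region_intervals(g, flank, chrom_len)
        for li, label in enumerate(GENIC_LABELS):
            for s, e in regions[label]:
                by_chrom.setdefault(g.chrom, []).append((s, e, gi, li))
    arrays: dict[str, tuple[np.ndarray, ...]] = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        a = np.asarray(rows, dtype=np.int64)
        arrays[chrom] = (a[:, 0], a[:, 1], a[:, 2], a[:, 3])

    hits: dict[int, tuple[set[str], set[str]]] = {}
    for p in peaks:
        got = arrays.get(p.interval.chrom)
        if got is None:
            continue
        starts, ends, gidx, lidx = got
        sel = (starts < p.interval.end) & (ends > p.interval.start)
        for gi, li in zip(gidx[sel], lidx[sel]):
            labs, pids = hits.setdefault(int(gi), (set(), set()))
            labs.add(GENIC_LABELS[int(li)])
            pids.add(p.name or f"{p.interval.chrom}:{p.interval.start}-{p.interval.end}")

    out = [
        PeakGeneAssociation(
            gene_id=genes[gi].gene_id,
            labels=frozenset(labs),
            peak_ids=tuple(sorted(pids)),
        )
        for gi, (labs, pids) in hits.items()
    ]
    out.sort(key=lambda a: a.gene_id)
    return out


def peak_region_percentages(
    associations: list[PeakGeneAssociation], n_genes_associated: int | None = None
) -> dict[str, float]:
    """Percent of peak-associated genes carrying each region label."""
    if n_genes_associated is None:
        n_genes_associated = len(associations)
    if n_genes_associated < 1:
        raise ValueError("need at least one associated gene")
    out = {}
    for label in GENIC_LABELS:
        k = sum(1 for a in associations if label in a.labels)
        out[label] = 100.0 * k / n_genes_associated
    return out


def peak_summary_stats(peaks: list[Peak]) -> dict[str, float]:
    """Peak count, mean length and total length (bp)."""
    n = len(peaks)
    if n == 0:
        return {"n": 0, "mean_length_bp": 0.0, "total_length_bp": 0, "empty": True}
    lengths = np.asarray([p.length for p in peaks])
    return {
        "n": n,
        "mean_length_bp": float(lengths.mean()),
        "total_length_bp": int(lengths.sum()),
        "empty": False,
    }


def saturation_curve(
    reads: ReadSet,
    fractions: list[float],
    peak_regions: list,
    seed: int,
) -> dict[float, float]:
    """Mean tag density over fixed peak regions under read subsampling.

    For each fraction, reads are subsampled without replacement (seeded)
    and the density = (subsampled 5' ends inside the peak regions) / (total
    peak bp) is recorded.  Peak regions come from the full data and are not
    re-called per fraction.  Densities are linear in the fraction in
    expectation, so the curve is non-decreasing in expectation.
    """
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    # peak regions as per-chromosome interval sets
    per_chrom_pairs: dict[str, list[tuple[int, int]]] = {}
    for region in peak_regions:
        interval = region.interval if isinstance(region, Peak) else region
        per_chrom_pairs.setdefault(interval.chrom, []).append((interval.start, interval.end))
    sets = {c: iv.make(p) for c, p in per_chrom_pairs.items()}
    total_bp = sum(iv.total_length(s) for s in sets.values())
    if total_bp == 0:
        raise ValueError("empty peak regions")

    n = len(reads)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)  # one permutation; prefixes give nested subsamples
    curve: dict[float, float] = {}
    for f in sorted(fractions):
        k = n if f == 1.0 else int(round(f * n))
        sub = reads.subset(order[:k])
        inside = 0
        for chrom, pos in sub.per_chrom().items():
            if chrom in sets:
                inside += iv.count_in(sets[chrom], pos)
        curve[f] = inside / total_bp
    return curve
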