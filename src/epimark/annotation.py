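"""Five-way genome partition: up20K, exon, intron, down20K, intergenic.

Each gene contributes, in transcription orientation, a 20 kb (configurable)
flank upstream of its TSS (``up20K``), its exons, its introns (span minus
exons) and a 20 kb flank downstream of its TES (``down20K``); everything
else is intergenic.  Flanks are clipped at chromosome edges.

Two modes:

* ``multilabel`` (default) — a base pair may carry several labels (an
  upstream flank of one gene can run through an intron of another), so
  label fractions can sum past 1.  This is how region percentages that sum
  to ~107% of the genome arise and is the convention used for read/peak
  distribution figures.
* ``exclusive`` — labels are made disjoint by the precedence
  exon > intron > up20K > down20K, and together with intergenic they tile
  the genome exactly once.  Used wherever a true partition is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv
from .core import GeneModel

log = logging.getLogger(__name__)

GENIC_LABELS = ("up20K", "exon", "intron", "down20K")
ALL_LABELS = GENIC_LABELS + ("intergenic",)

__all__ = [
    "GENIC_LABELS",
    "ALL_LABELS",
    "RegionPartitionIndex",
    "gene_region_intervals",
    "build_region_partition",
    "region_genome_fractions",
]


def gene_region_intervals(gene: GeneModel, flank: int, chrom_len: int | None = None):
    """Raw (unclipped overlap-unaware) region intervals for one gene.

    Returns ``{label: [(start, end), ...]}`` clipped to ``[0, chrom_len)``.
    The upstream flank sits before the TSS *in transcription orientation*:
    for a '-' gene it lies to the right of the span.
    """
    s, e = gene.span.start, gene.span.end
    if gene.strand == "+":
        up = (s - flank, s)
        down = (e, e + flank)
    else:
        up = (e, e + flank)
        down = (s - flank, s)
    exons = [(ex.start, ex.end) for ex in gene.exons]
    exon_set = iv.make(exons)
    intron_set = iv.subtract(iv.make([(s, e)]), exon_set)
    out = {
        "up20K": [up],
        "exon": list(zip(exon_set[0], exon_set[1])),
        "intron": list(zip(intron_set[0], intron_set[1])),
        "down20K": [down],
    }
    hi = chrom_len if chrom_len is not None else None
    clipped = {}
    for label, pairs in out.items():
        keep = []
        for a, b in pairs:
            a2 = max(0, int(a))
            b2 = min(int(b), hi) if hi is not None else int(b)
            if b2 > a2:
                keep.append((a2, b2))
        clipped[label] = keep
    return clipped


@dataclass
class RegionPartitionIndex:
    """Genome-wide region labelling (see module docstring).

    ``labels[label][chrom]`` is a canonical interval set.  In exclusive mode
    an explicit ``intergenic`` label is stored and labels are disjoint.
    """

    flank: int
    mode: str
    genome_sizes: dict[str, int]
    labels: dict[str, dict[str, iv.IntervalSet]] = field(default_factory=dict)

    @property
    def genome_bp(self) -> int:
        return int(sum(self.genome_sizes.values()))

    def label_set(self, label: str, chrom: str) -> iv.IntervalSet:
        return self.labels.get(label, {}).get(chrom, iv.EMPTY)

    def labels_at(self, chrom: str, positions: np.ndarray) -> dict[str, np.ndarray]:
        """Per-label boolean membership arrays for the given positions."""
        out = {}
        for label in self.labels:
            out[label] = iv.contains(self.label_set(label, chrom), positions)
        return out

    def labeled_bp(self, label: str) -> int:
        return sum(iv.total_length(s) for s in self.labels.get(label, {}).values())

    def to_bed_frame(self) -> pd.DataFrame:
        """Flat BED-like table (chrom, start, end, label) for export."""
        rows = []
        for label in sorted(self.labels):
            for chrom in sorted(self.labels[label]):
                starts, ends = self.labels[label][chrom]
                for s, e in zip(starts, ends):
                    rows.append((chrom, int(s), int(e), label))
        rows.sort()
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def build_region_partition(
    genes: list[GeneModel],
    genome_sizes: dict[str, int],
    flank: int = 20_000,
    mode: str = "multilabel",
) -> RegionPartitionIndex:
    """Build the five-region labelling structure over the genome."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if mode not in ("multilabel", "exclusive"):
        raise ValueError(f"unknown mode {mode!r}")
    for g in genes:
        if g.chrom not in genome_sizes:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        if g.span.end > genome_sizes[g.chrom]:
            log.warning("gene %s extends past chromosome end; clipped", g.gene_id)

    raw: dict[str, dict[str, list]] = {lab: {} for lab in GENIC_LABELS}
    for g in genes:
        per = gene_region_intervals(g, flank, genome_sizes[g.chrom])
        for label, pairs in per.items():
            raw[label].setdefault(g.chrom, []).extend(pairs)

    labels: dict[str, dict[str, iv.IntervalSet]] = {}
    for label in GENIC_LABELS:
        labels[label] = {c: iv.make(p) for c, p in raw[label].items()}

    if mode == "exclusive":
        # precedence exon > intron > up20K > down20K; remainder intergenic
        order = ["exon", "intron", "up20K", "down20K"]
        chroms = sorted(genome_sizes)
        taken: dict[str, iv.IntervalSet] = {c: iv.EMPTY for c in chroms}
        for label in order:
            for c in chroms:
                own = iv.subtract(labels[label].get(c, iv.EMPTY), taken[c])
                labels[label][c] = own
                taken[c] = iv.union(taken[c], own)
        labels["intergenic"] = {
            c: iv.subtract(iv.make([(0, genome_sizes[c])]), taken[c]) for c in chroms
        }

    return RegionPartitionIndex(flank=flank, mode=mode, genome_sizes=dict(genome_sizes), labels=labels)


def region_genome_fractions(index: RegionPartitionIndex) -> dict[str, float]:
    """Fraction of the genome carrying each label.

    Exclusive mode: fractions (with intergenic) sum to exactly 1.
    Multilabel mode: intergenic is the complement of the union of the four
    genic labels, so the sum can exceed 1 when labels overlap.
    """
    G = index.genome_bp
    out = {lab: index.labeled_bp(lab) / G for lab in GENIC_LABELS}
    if "intergenic" in index.labels:
        out["intergenic"] = index.labeled_bp("intergenic") / G
    else:
        covered = 0
        for chrom, size in index.genome_sizes.items():
            u = iv.EMPTY
            for lab in GENIC_LABELS:
                u = iv.union(u, index.label_set(lab, chrom))
            covered += iv.total_length(u)
        out["intergenic"] = (G - covered) / G
    return out
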