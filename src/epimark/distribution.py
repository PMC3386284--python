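"""Read distribution over the five region classes and abundance normalization.

Each read is a point event at its 5' position.  In multilabel mode a read
increments every label covering that base (so label counts can sum past the
number of reads, but each label's percentage — computed over N reads — stays
interpretable on its own); in exclusive mode it increments exactly one.
A read covered by no genic label, or on a chromosome absent from the index,
counts as intergenic (the latter with a warning tally).

*Abundance* of a region class is its read percentage divided by its genome
percentage; 1 means reads occur at genome-average density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import ALL_LABELS, GENIC_LABELS, RegionPartitionIndex, region_genome_fractions
from .core import ReadSet

log = logging.getLogger(__name__)

__all__ = ["RegionCountSummary", "assign_reads_to_regions", "abundance_normalize"]


@dataclass
class RegionCountSummary:
    counts: dict[str, int]
    read_pct: dict[str, float]
    genome_pct: dict[str, float]
    abundance: dict[str, float]
    n_reads: int
    n_unknown_chrom: int = 0
    mode: str = "multilabel"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                lab,
                self.counts.get(lab, 0),
                self.read_pct.get(lab, 0.0),
                self.genome_pct.get(lab, 0.0),
                self.abundance.get(lab, float("nan")),
            )
            for lab in ALL_LABELS
        ]
        return pd.DataFrame(
            rows, columns=["label", "count", "read_pct", "genome_pct", "abundance"]
        )


def abundance_normalize(
    read_pct: dict[str, float], genome_pct: dict[str, float]
) -> dict[str, float]:
    """abundance(label) = read % / genome %.

    A label with reads but zero genome share is undefined and raises.
    """
    out = {}
    for lab, rp in read_pct.items():
        gp = genome_pct.get(lab, 0.0)
        if gp == 0.0:
            if rp > 0:
                raise ValueError(f"label {lab!r} has reads but zero genome share")
            continue
        out[lab] = rp / gp
    return out


def assign_reads_to_regions(
    reads: ReadSet, index: RegionPartitionIndex
) -> RegionCountSummary:
    """Count reads per region class and derive percentages and abundances."""
    n = len(reads)
    counts = {lab: 0 for lab in ALL_LABELS}
    n_unknown = 0
    for chrom, pos in reads.per_chrom().items():
        if len(pos) == 0:
            continue
        if chrom not in index.genome_sizes:
            n_unknown += len(pos)
            counts["intergenic"] += len(pos)
            continue
        if index.mode == "exclusive":
            assigned = np.zeros(len(pos), dtype=bool)
            for lab in ("exon", "intron", "up20K", "down20K"):
                hit = np.asarray(
                    index.labels_at(chrom, pos).get(lab, np.zeros(len(pos), bool))
                )
                # exclusive sets are disjoint, so summing per label is safe
                counts[lab] += int(hit.sum())
                assigned |= hit
            counts["intergenic"] += int((~assigned).sum())
        else:
            membership = index.labels_at(chrom, pos)
            any_label = np.zeros(len(pos), dtype=bool)
            for lab in GENIC_LABELS:
                hit = membership.get(lab, np.zeros(len(pos), bool))
                counts[lab] += int(hit.sum())
                any_label |= hit
            counts["intergenic"] += int((~any_label).sum())
    if n_unknown:
        log.warning("%d reads on chromosomes absent from the partition", n_unknown)

    read_pct = {lab: (100.0 * c / n if n else 0.0) for lab, c in counts.items()}
    genome_pct = {lab: 100.0 * f for lab, f in region_genome_fractions(index).items()}
    abundance = abundance_normalize(
        {lab: p for lab, p in read_pct.items() if genome_pct.get(lab, 0) > 0 or p > 0},
        genome_pct,
    )
    return RegionCountSummary(
        counts=counts,
        read_pct=read_pct,
        genome_pct=genome_pct,
        abundance=abundance,
        n_reads=n,
        n_unknown_chrom=n_unknown,
        mode=index.mode,
    )
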