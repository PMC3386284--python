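"""Core domain types shared by every pipeline stage.

All genomic coordinates in this package are 0-based, half-open
(``[start, end)``), the BED convention.  External formats that use other
conventions (MACS 1.4 peak tables are 1-based inclusive) are converted on
ingest by :mod:`epimark.io` and never seen elsewhere.

Sequencing reads are point events: a read is counted at the position of its
5' end only.  The read length is retained as metadata but never used for
overlap arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "ReadAlignment",
    "ReadSet",
    "Peak",
    "CpRecord",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share at least one base pair."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene: stranded span plus non-overlapping sorted exons within it.

    The TSS/TES are derived from the span by the strand rule: on '+' the TSS
    is ``span.start`` and the TES ``span.end - 1``; on '-' they swap.  Both
    are single base positions (0-based).
    """

    gene_id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: span must be stranded")
        if len(self.exons) < 1:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.span.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(f"gene {self.gene_id}: exon outside span")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end
        if self.span.length < 2:
            raise ValueError(f"gene {self.gene_id}: span too short (tss == tes)")

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1

    @property
    def tes(self) -> int:
        return self.span.end - 1 if self.strand == "+" else self.span.start

    @property
    def length(self) -> int:
        return self.span.length

    def oriented_offset(self, pos: int) -> int:
        """Offset of ``pos`` from the TSS in transcription orientation.

        Negative offsets are biologically upstream regardless of strand.
        """
        return pos - self.tss if self.strand == "+" else self.tss - pos


@dataclass(frozen=True)
class ReadAlignment:
    """One uniquely mapped ChIP tag, point-counted at its 5' end."""

    chrom: str
    pos5: int
    strand: str = "+"
    length: int = 49

    def __post_init__(self) -> None:
        if self.pos5 < 0:
            raise ValueError("pos5 must be >= 0")
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


class ReadSet(Sequence):
    """Array-backed collection of :class:`ReadAlignment` records.

    Behaves as a sequence of ``ReadAlignment`` but stores chromosome codes,
    5' positions and strands as numpy arrays so that multi-million read sets
    remain cheap.  ``per_chrom()`` exposes sorted 5' position arrays, the
    representation every counting stage consumes.
    """

    def __init__(
        self,
        chrom_names: Sequence[str],
        chrom_codes: np.ndarray,
        pos5: np.ndarray,
        strand_is_minus: np.ndarray,
        length: int = 49,
        n_rejected: int = 0,
    ) -> None:
        self.chrom_names = list(chrom_names)
        self.chrom_codes = np.asarray(chrom_codes, dtype=np.int32)
        self.pos5 = np.asarray(pos5, dtype=np.int64)
        self.strand_is_minus = np.asarray(strand_is_minus, dtype=bool)
        self.length = int(length)
        self.n_rejected = int(n_rejected)
        if not (len(self.chrom_codes) == len(self.pos5) == len(self.strand_is_minus)):
            raise ValueError("array length mismatch")
        self._per_chrom: dict[str, np.ndarray] | None = None

    @classmethod
    def from_records(cls, records: Sequence[ReadAlignment], length: int | None = None) -> "ReadSet":
        names: list[str] = []
        index: dict[str, int] = {}
        codes = np.empty(len(records), dtype=np.int32)
        pos = np.empty(len(records), dtype=np.int64)
        minus = np.empty(len(records), dtype=bool)
        for i, r in enumerate(records):
            if r.chrom not in index:
                index[r.chrom] = len(names)
                names.append(r.chrom)
            codes[i] = index[r.chrom]
            pos[i] = r.pos5
            minus[i] = r.strand == "-"
        if length is None:
            length = records[0].length if records else 49
        return cls(names, codes, pos, minus, length=length)

    def __len__(self) -> int:
        return len(self.pos5)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        return ReadAlignment(
            chrom=self.chrom_names[self.chrom_codes[i]],
            pos5=int(self.pos5[i]),
            strand="-" if self.strand_is_minus[i] else "+",
            length=self.length,
        )

    def __iter__(self) -> Iterator[ReadAlignment]:
        for i in range(len(self)):
            yield self[i]

    def per_chrom(self) -> dict[str, np.ndarray]:
        """Sorted 5'-position array per chromosome (cached)."""
        if self._per_chrom is None:
            out: dict[str, np.ndarray] = {}
            for code, name in enumerate(self.chrom_names):
                p = self.pos5[self.chrom_codes == code]
                out[name] = np.sort(p)
            self._per_chrom = out
        return self._per_chrom

    def subset(self, idx: np.ndarray) -> "ReadSet":
        return ReadSet(
            self.chrom_names,
            self.chrom_codes[idx],
            self.pos5[idx],
            self.strand_is_minus[idx],
            length=self.length,
        )


@dataclass(frozen=True)
class Peak:
    """A called enrichment region with its summit and MACS-style scores.

    ``summit`` is an absolute base position inside ``interval``.
    ``p_value`` is stored as printed by the caller; ``p_is_neglog10`` records
    the dialect (MACS 1.4 prints ``-10*log10(pvalue)``).
    """

    interval: GenomicInterval
    summit: int
    p_value: float
    fold_enrichment: float
    name: str = ""
    p_is_neglog10: bool = True

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit outside peak interval")
        if self.fold_enrichment <= 0:
            raise ValueError("fold_enrichment must be > 0")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class CpRecord:
    """One qPCR crossing-point measurement."""

    sample_id: str
    primer_site: str
    template: str  # "chip" or "input"
    cp: float
    input_ng: float | None = None

    def __post_init__(self) -> None:
        if self.cp <= 0:
            raise ValueError("cp must be > 0")
        if self.template not in ("chip", "input"):
            raise ValueError(f"template must be 'chip' or 'input', got {self.template!r}")
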