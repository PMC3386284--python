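"""Readers and writers for every external format the pipeline touches.

Formats
-------
* BED3/BED6 for mapped reads (native coordinates, 0-based half-open).
* A genePred-dialect tab table for gene models:
  ``gene_id  chrom  strand  txStart  txEnd  exonStarts  exonEnds``
  (comma-separated exon lists, 0-based half-open).
* MACS 1.4 ``.xls`` peak tables (1-based inclusive, summit relative to
  start; converted to internal 0-based half-open absolute coordinates on
  ingest — the conversion is a bijection).
* Transcript FASTA (via Biopython).
* Plain TSV for tag-count tables and qPCR Cp tables.

Malformed lines raise :class:`FormatError` naming the line number; records
that merely violate a value invariant (start >= end, fold_enrichment <= 0)
are dropped and tallied.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import CpRecord, GeneModel, GenomicInterval, Peak, ReadSet

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_bed_reads",
    "write_bed_reads",
    "read_gene_table",
    "write_gene_table",
    "read_macs_peaks",
    "write_macs_peaks",
    "write_graph_track",
    "read_transcripts",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_tag_counts",
    "write_tag_counts",
    "read_cp_table",
]


class FormatError(ValueError):
    """A structurally malformed input line (carries the 1-based line number)."""

    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------------- reads

def read_bed_reads(path, read_length: int = 49) -> ReadSet:
    """Parse a BED3/BED6 file of mapped reads into a :class:`ReadSet`.

    The 5' position of a '+' read is the BED start; of a '-' read the BED
    ``end - 1``.  Records without a strand column default to '+'.  Records
    with ``start >= end`` are rejected (counted in ``ReadSet.n_rejected``).
    """
    names: list[str] = []
    index: dict[str, int] = {}
    codes, pos5, minus = [], [], []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(path, lineno, "expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(path, lineno, f"non-integer coordinate: {exc}")
            if start >= end or start < 0:
                n_rejected += 1
                continue
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand not in ("+", "-"):
                strand = "+"  # BED3 has no strand; default with a warning
            if chrom not in index:
                index[chrom] = len(names)
                names.append(chrom)
            codes.append(index[chrom])
            pos5.append(start if strand == "+" else end - 1)
            minus.append(strand == "-")
    if n_rejected:
        log.warning("%s: rejected %d records with start >= end", path, n_rejected)
    return ReadSet(
        names,
        np.asarray(codes, dtype=np.int32),
        np.asarray(pos5, dtype=np.int64),
        np.asarray(minus, dtype=bool),
        length=read_length,
        n_rejected=n_rejected,
    )


def write_bed_reads(path, reads: ReadSet) -> None:
    """Write reads as BED6; inverse of :func:`read_bed_reads`."""
    L = reads.length
    with open(path, "w") as fh:
        for i in range(len(reads)):
            chrom = reads.chrom_names[reads.chrom_codes[i]]
            p = int(reads.pos5[i])
            if reads.strand_is_minus[i]:
                start, end, strand = p - L + 1, p + 1, "-"
            else:
                start, end, strand = p, p + L, "+"
            fh.write(f"{chrom}\t{start}\t{end}\t.\t0\t{strand}\n")


# ---------------------------------------------------------------------- genes

def read_gene_table(path) -> list[GeneModel]:
    """Parse the genePred-dialect gene table (see module docstring)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise FormatError(path, lineno, "expected 7 columns")
            gid, chrom, strand = fields[0], fields[1], fields[2]
            try:
                tx_start, tx_end = int(fields[3]), int(fields[4])
                ex_starts = [int(x) for x in fields[5].rstrip(",").split(",")]
                ex_ends = [int(x) for x in fields[6].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(path, lineno, f"bad integer field: {exc}")
            if len(ex_starts) != len(ex_ends):
                raise FormatError(path, lineno, "exonStarts/exonEnds arity mismatch")
            try:
                exons = tuple(
                    GenomicInterval(chrom, s, e, strand)
                    for s, e in zip(ex_starts, ex_ends)
                )
                genes.append(
                    GeneModel(gid, GenomicInterval(chrom, tx_start, tx_end, strand), exons)
                )
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc))
    return genes


def write_gene_table(path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttxStart\ttxEnd\texonStarts\texonEnds\n")
        for g in genes:
            es = ",".join(str(e.start) for e in g.exons)
            ee = ",".join(str(e.end) for e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.span.start}\t{g.span.end}\t{es}\t{ee}\n"
            )


# ---------------------------------------------------------------------- peaks

_MACS_HEADER = [
    "chr", "start", "end", "length", "summit", "tags",
    "-10*log10(pvalue)", "fold_enrichment", "FDR(%)",
]


def read_macs_peaks(path) -> list[Peak]:
    """Parse a MACS 1.4 ``.xls`` peak table into internal coordinates.

    Input is 1-based inclusive with the summit relative to the peak start
    (1-based): a row ``start=1001, end=1200, summit=120`` becomes the
    interval ``[1000, 1200)`` with absolute summit 1119.  Header/comment
    lines start with '#' or 'chr'.  Rows with non-positive fold enrichment
    are rejected and tallied; a header-only file yields an empty list.
    """
    peaks: list[Peak] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chr\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(path, lineno, "expected >= 8 MACS columns")
            try:
                chrom = fields[0]
                start1, end1 = int(fields[1]), int(fields[2])
                length = int(fields[3])
                summit_rel = int(fields[4])
                neglog_p = float(fields[6])
                fold = float(fields[7])
            except ValueError as exc:
                raise FormatError(path, lineno, f"bad field: {exc}")
            start0, end0 = start1 - 1, end1  # 1-based incl -> 0-based half-open
            if length != end1 - start1 + 1:
                log.warning("%s:%d: length column inconsistent with coordinates", path, lineno)
            if fold <= 0:
                n_rejected += 1
                continue
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start0, end0),
                    summit=start0 + summit_rel - 1,
                    p_value=neglog_p,
                    fold_enrichment=fold,
                    name=f"peak_{len(peaks) + 1}",
                )
            )
    if n_rejected:
        log.warning("%s: rejected %d peaks with fold_enrichment <= 0", path, n_rejected)
    return peaks


def write_macs_peaks(path, peaks: list[Peak]) -> None:
    """Write peaks in the MACS 1.4 xls dialect; inverse of :func:`read_macs_peaks`."""
    with open(path, "w") as fh:
        fh.write("# epimark peak export (MACS 1.4 dialect)\n")
        fh.write("\t".join(_MACS_HEADER) + "\n")
        for p in peaks:
            start1 = p.interval.start + 1
            end1 = p.interval.end
            length = end1 - start1 + 1
            summit_rel = p.summit - p.interval.start + 1
            fh.write(
                f"{p.interval.chrom}\t{start1}\t{end1}\t{length}\t{summit_rel}\t0\t"
                f"{p.p_value:.2f}\t{p.fold_enrichment:.2f}\t0.00\n"
            )


# ---------------------------------------------------------------- graph track

def write_graph_track(reads: ReadSet, window: int = 50) -> pd.DataFrame:
    """Bin read 5' positions into non-overlapping fixed-width summary windows.

    Returns a table ``(chrom, window_start, count)``; zero-count windows are
    omitted.  Total counts are conserved for any window size.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rows = []
    for chrom in sorted(reads.per_chrom()):
        pos = reads.per_chrom()[chrom]
        if len(pos) == 0:
            continue
        bins = pos // window
        uniq, counts = np.unique(bins, return_counts=True)
        for b, c in zip(uniq, counts):
            rows.append((chrom, int(b) * window, int(c)))
    return pd.DataFrame(rows, columns=["chrom", "window_start", "count"])


# --------------------------------------------------------------------- others

def read_transcripts(path) -> dict[str, str]:
    """Transcript FASTA -> {gene_id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(path, lineno, "expected 'chrom<TAB>size'")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(path, sizes: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_tag_counts(path) -> pd.DataFrame:
    """TSV with columns gene_id, count[, tpm]."""
    return pd.read_csv(path, sep="\t")


def write_tag_counts(path, counts: dict[str, int], tpm: dict[str, float] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcount" + ("\ttpm" if tpm is not None else "") + "\n")
        for gid in sorted(counts):
            if tpm is not None:
                fh.write(f"{gid}\t{counts[gid]}\t{tpm.get(gid, 0.0):.6f}\n")
            else:
                fh.write(f"{gid}\t{counts[gid]}\n")


def read_cp_table(path) -> list[CpRecord]:
    """TSV with columns sample_id, primer_site, template, cp[, input_ng]."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        records.append(
            CpRecord(
                sample_id=str(row["sample_id"]),
                primer_site=str(row["primer_site"]),
                template=str(row["template"]),
                cp=float(row["cp"]),
                input_ng=float(row["input_ng"]) if "input_ng" in df.columns and pd.notna(row.get("input_ng")) else None,
            )
        )
    return records


def validate_file(path) -> str:
    """Best-effort format validation used by ``epimark io validate``.

    Returns the detected kind; raises on failure.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        read_bed_reads(path)
        return "bed"
    if suffix == ".xls":
        read_macs_peaks(path)
        return "macs-peaks"
    if suffix in (".fa", ".fasta"):
        read_transcripts(path)
        return "fasta"
    if suffix == ".sizes":
        read_chrom_sizes(path)
        return "chrom-sizes"
    if suffix in (".tsv", ".txt"):
        with open(path) as fh:
            header = fh.readline()
        if header.startswith("gene_id\tchrom"):
            read_gene_table(path)
            return "gene-table"
        if header.startswith("sample_id"):
            read_cp_table(path)
            return "cp-table"
        if header.startswith("gene_id"):
            read_tag_counts(path)
            return "tag-counts"
        if len(header.split("\t")) == 2:
            read_chrom_sizes(path)
            return "chrom-sizes"
    raise FormatError(path, 0, "unrecognized format")
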