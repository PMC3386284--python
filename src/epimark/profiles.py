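"""Tag-density profile matrices in three geometries.

* **TSS** — fixed windows (default 50 bp) tiling ``[TSS-span, TSS+span)`` in
  transcription orientation; '-' strand genes are mirrored so negative
  offsets are always biologically upstream.
* **Metagene** — 20 upstream 1 kb flank bins, 20 gene-body bins of 5% of the
  gene length each, 20 downstream 1 kb flank bins (60 columns).  Densities
  divide each bin's count by its own base-pair size, which removes the
  bin-size effect: uniform reads give a flat profile.
* **Promoter** — 500 bp windows tiling ``[TSS-5000, TSS)`` (10 columns).

Windows are left-closed right-open in oriented offset space; the TSS sits at
the left edge of the first downstream column.  A read contributes to the
column containing its 5' position; read strand is ignored (nucleosomal ChIP
signal is strand-agnostic).

Columns whose absolute genomic extent leaves the chromosome are flagged
missing and excluded from aggregate averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneModel, ReadSet

log = logging.getLogger(__name__)

__all__ = [
    "ProfileMatrix",
    "tss_profile_matrix",
    "metagene_profile",
    "promoter_window_densities",
    "aggregate_density",
]


@dataclass
class ProfileMatrix:
    """Genes x windows tag-count matrix with window geometry metadata.

    ``counts[i, j]`` is the number of read 5' ends in window ``j`` of gene
    ``i``; ``bp[i, j]`` that window's length in base pairs (per-gene for the
    metagene body bins); ``valid[i, j]`` is False where the window leaves
    the chromosome.  ``col_offsets`` holds the left oriented offset of each
    column for fixed-window geometries and ``col_labels`` a printable label
    per column for all geometries.
    """

    gene_ids: list[str]
    geometry: str
    col_labels: list[str]
    counts: np.ndarray
    bp: np.ndarray
    valid: np.ndarray
    col_offsets: np.ndarray | None = None
    library_size: int = 0

    def __post_init__(self) -> None:
        if self.counts.shape != self.bp.shape or self.counts.shape != self.valid.shape:
            raise ValueError("matrix shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cols(self) -> int:
        return self.counts.shape[1]

    def row_index(self, gene_ids) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.asarray([pos[g] for g in gene_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in profile matrix")

    def densities(self, rpm: bool = False) -> np.ndarray:
        """Per-gene tag densities (tags/bp); NaN where the window is missing.

        With ``rpm=True`` densities are additionally scaled to a library
        size of one million reads (for between-sample comparisons).
        """
        d = np.where(self.valid, self.counts / self.bp, np.nan)
        if rpm:
            if self.library_size <= 0:
                raise ValueError("library_size unknown; cannot scale to RPM")
            d = d * (1e6 / self.library_size)
        return d

    def to_frame(self, rpm: bool = False) -> pd.DataFrame:
        return pd.DataFrame(self.densities(rpm=rpm), index=self.gene_ids, columns=self.col_labels)


def _oriented_hits(pos: np.ndarray, gene: GeneModel, lo_off: int, hi_off: int) -> np.ndarray:
    """Oriented offsets (in [lo_off, hi_off)) of reads around one gene."""
    tss = gene.tss
    if gene.strand == "+":
        lo, hi = tss + lo_off, tss + hi_off
        i0, i1 = np.searchsorted(pos, lo), np.searchsorted(pos, hi)
        return pos[i0:i1] - tss
    # '-' strand: offset = tss - p; p in (tss - hi_off, tss - lo_off]
    lo, hi = tss - hi_off + 1, tss - lo_off + 1
    i0, i1 = np.searchsorted(pos, lo), np.searchsorted(pos, hi)
    return tss - pos[i0:i1]


def _fixed_window_matrix(
    reads: ReadSet,
    genes: list[GeneModel],
    window: int,
    lo_off: int,
    hi_off: int,
    geometry: str,
    genome_sizes: dict[str, int] | None,
) -> ProfileMatrix:
    if (hi_off - lo_off) % window != 0:
        raise ValueError("span must be a multiple of window")
    ncol = (hi_off - lo_off) // window
    per_chrom = reads.per_chrom()
    counts = np.zeros((len(genes), ncol), dtype=np.int64)
    bp = np.full((len(genes), ncol), float(window))
    valid = np.ones((len(genes), ncol), dtype=bool)
    edges = lo_off + window * np.arange(ncol)

    for i, g in enumerate(genes):
        pos = per_chrom.get(g.chrom, np.empty(0, dtype=np.int64))
        off = _oriented_hits(pos, g, lo_off, hi_off)
        if len(off):
            cols = (off - lo_off) // window
            counts[i] = np.bincount(cols, minlength=ncol)
        # flag columns leaving the chromosome
        chrom_len = genome_sizes.get(g.chrom) if genome_sizes else None
        for j in range(ncol):
            o0, o1 = edges[j], edges[j] + window
            if g.strand == "+":
                a, b = g.tss + o0, g.tss + o1
            else:
                a, b = g.tss - o1 + 1, g.tss - o0 + 1
            if a < 0 or (chrom_len is not None and b > chrom_len):
                valid[i, j] = False
    n_dropped_cols = int((~valid).sum())
    if n_dropped_cols:
        log.info("%s profile: %d gene-windows leave the chromosome (masked)", geometry, n_dropped_cols)
    labels = [f"[{e},{e + window})" for e in edges]
    return ProfileMatrix(
        gene_ids=[g.gene_id for g in genes],
        geometry=geometry,
        col_labels=labels,
        counts=counts,
        bp=bp,
        valid=valid,
        col_offsets=edges,
        library_size=len(reads),
    )


def tss_profile_matrix(
    reads: ReadSet,
    genes: list[GeneModel],
    window: int = 50,
    span: int = 20_000,
    genome_sizes: dict[str, int] | None = None,
) -> ProfileMatrix:
    """Fixed-window profile over ``[TSS-span, TSS+span)`` per gene."""
    return _fixed_window_matrix(reads, genes, window, -span, span, "tss", genome_sizes)


def promoter_window_densities(
    reads: ReadSet,
    genes: list[GeneModel],
    window: int = 500,
    span: int = 5_000,
    genome_sizes: dict[str, int] | None = None,
) -> ProfileMatrix:
    """500 bp windows tiling the upstream promoter region ``[TSS-span, TSS)``."""
    return _fixed_window_matrix(reads, genes, window, -span, 0, "promoter", genome_sizes)


def metagene_profile(
    reads: ReadSet,
    genes: list[GeneModel],
    body_bins: int = 20,
    flank_kb: int = 20,
    genome_sizes: dict[str, int] | None = None,
) -> ProfileMatrix:
    """Rescaled gene-body profile: 1 kb flank bins + percent-of-body bins.

    Genes shorter than ``body_bins`` bp are excluded (logged).  Body bin
    base-pair sizes are the exact gene length divided by ``body_bins``.
    """
    kept = [g for g in genes if g.length >= body_bins]
    dropped = len(genes) - len(kept)
    if dropped:
        log.warning("metagene: excluded %d genes shorter than %d bp", dropped, body_bins)
    flank = flank_kb * 1000
    ncol = 2 * flank_kb + body_bins
    per_chrom = reads.per_chrom()
    counts = np.zeros((len(kept), ncol), dtype=np.int64)
    bp = np.empty((len(kept), ncol))
    valid = np.ones((len(kept), ncol), dtype=bool)

    for i, g in enumerate(kept):
        L = g.length
        pos = per_chrom.get(g.chrom, np.empty(0, dtype=np.int64))
        off = _oriented_hits(pos, g, -flank, L + flank)
        if len(off):
            cols = np.empty(len(off), dtype=np.int64)
            up = off < 0
            body = (off >= 0) & (off < L)
            down = off >= L
            cols[up] = (off[up] + flank) // 1000
            cols[body] = flank_kb + np.minimum(
                (off[body] * body_bins) // L, body_bins - 1
            )
            cols[down] = flank_kb + body_bins + (off[down] - L) // 1000
            counts[i] = np.bincount(cols, minlength=ncol)
        bp[i, :flank_kb] = 1000.0
        bp[i, flank_kb : flank_kb + body_bins] = L / body_bins
        bp[i, flank_kb + body_bins :] = 1000.0
        # flank bins beyond the chromosome are masked
        chrom_len = genome_sizes.get(g.chrom) if genome_sizes else None
        for j in range(flank_kb):
            o0, o1 = -flank + j * 1000, -flank + (j + 1) * 1000
            a, b = (g.tss + o0, g.tss + o1) if g.strand == "+" else (g.tss - o1 + 1, g.tss - o0 + 1)
            if a < 0 or (chrom_len is not None and b > chrom_len):
                valid[i, j] = False
        for j in range(flank_kb):
            o0, o1 = L + j * 1000, L + (j + 1) * 1000
            a, b = (g.tss + o0, g.tss + o1) if g.strand == "+" else (g.tss - o1 + 1, g.tss - o0 + 1)
            if a < 0 or (chrom_len is not None and b > chrom_len):
                valid[i, flank_kb + body_bins + j] = False

    labels = (
        [f"up{flank_kb - j}kb" for j in range(flank_kb)]
        + [f"body{100 * j // body_bins}-{100 * (j + 1) // body_bins}%" for j in range(body_bins)]
        + [f"down{j + 1}kb" for j in range(flank_kb)]
    )
    return ProfileMatrix(
        gene_ids=[g.gene_id for g in kept],
        geometry="metagene",
        col_labels=labels,
        counts=counts,
        bp=bp,
        valid=valid,
        library_size=len(reads),
    )


def aggregate_density(
    matrix: ProfileMatrix, gene_set=None, rpm: bool = False
) -> np.ndarray:
    """Per-column mean tag density (tags/bp) over a gene set.

    The mean runs over non-missing rows only; an empty gene set is an error.
    """
    if gene_set is None:
        rows = np.arange(matrix.n_genes)
    else:
        gene_set = list(gene_set)
        if not gene_set:
            raise ValueError("empty gene set")
        rows = matrix.row_index(gene_set)
    if len(rows) == 0:
        raise ValueError("empty gene set")
    d = matrix.densities(rpm=rpm)[rows]
    with np.errstate(invalid="ignore"):
        return np.nanmean(d, axis=0)
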