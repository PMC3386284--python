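"""Synthetic genomes, expression and ChIP read sets with known truth.

The generator emulates the data structure the pipeline expects from a
repressive-mark (H3K27me3-like) ChIP-seq x tag-based expression study:

* a compact multi-chromosome genome with non-overlapping gene
  neighbourhoods (each gene owns its 20 kb flanks);
* per-gene expression: a fixed fraction of silent genes, log-normal TPM
  weights for the rest, multinomial tag counts per library;
* ChIP reads from an inhomogeneous Poisson process whose intensity couples
  *inversely* to expression through the repression coupling
  ``r(g) = descending expression rank / (n - 1)`` (silent genes maximal):

  .. math::

     \\lambda(x) = \\lambda_{bg}\\,[1 + r(g)(A\\,e^{-(x+2000)^2/2\\sigma_b^2}
                  + B\\,\\mathbf{1}_{[-\\text{flank},\\,0)}(x))]
                  \\,[1 - d\\,e^{-x^2/2w^2}]

  in oriented TSS offsets ``x``: a Gaussian promoter bump centred 2 kb
  upstream, a broad upstream plateau (silent genes carry elevated signal
  across the whole upstream region, as repressive domains do), and a
  nucleosome-depletion dip at the TSS, on a uniform background;
* a two-group ("parity"-style) design: a band of affected genes just above
  the median expression rank whose expression drops ``2^-delta`` in group B
  while their promoter intensity over oriented [-2000, -1000) is multiplied
  by ``f``.

Everything is driven by one seed through ``numpy.random.SeedSequence``
spawning, so outputs are byte-identical across runs.  The truth tables
(TPM, coupling r, affected genes) suffice to score every recovery test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, Peak, ReadSet

__all__ = [
    "SimulationConfig",
    "ExpressionTruth",
    "TwoGroupStudy",
    "simulate_gene_models",
    "simulate_expression",
    "simulate_chip_reads",
    "simulate_peaks",
    "simulate_two_group_study",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the default simulation (see docs/methods.md)."""

    seed: int = 0
    # genome
    n_chroms: int = 4
    chrom_length_bp: int = 30_000_000
    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (2000, 10_000)
    flank: int = 20_000
    # expression model
    fraction_silent: float = 0.3
    mu_log: float = 4.0
    sigma_log: float = 1.5
    depth_tags: int = 2_000_000
    # ChIP model
    depth_reads: int = 2_000_000
    bump_amplitude: float = 20.0  # A
    bump_center: int = -2000  # oriented offset of the promoter bump
    bump_sigma: float = 800.0
    broad_amplitude: float = 1.5  # B, upstream plateau coupled to r(g)
    tss_dip_depth: float = 0.8  # d
    tss_dip_width: float = 150.0
    read_length: int = 49
    # two-group design
    n_affected: int = 50
    expr_delta: float = 2.0  # affected TPM x 2^-delta in group B
    mark_fold: float = 2.0  # f, intensity multiplier on mark_window in group B
    mark_window: tuple[int, int] = (-2000, -1000)
    n_samples_per_group: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_silent < 1):
            raise ValueError("fraction_silent must be in [0, 1)")
        if not (0 <= self.tss_dip_depth < 1):
            raise ValueError("tss_dip_depth must be in [0, 1)")
        if min(self.bump_amplitude, self.broad_amplitude) < 0:
            raise ValueError("amplitudes must be >= 0")


# ----------------------------------------------------------------- gene models

def simulate_gene_models(config: SimulationConfig):
    """Place genes in per-gene slots so 20 kb flanks never overlap.

    Returns ``(genes, chrom_sizes)``.  Strands alternate; each gene gets
    1-5 exons tiling its span (first and last exon touch the span ends).
    """
    ss = np.random.SeedSequence(config.seed, spawn_key=(0,))
    rng = np.random.default_rng(ss)
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    l_min, l_max = config.gene_length_range
    margin = 1000
    need = 2 * config.flank + l_max + 2 * margin
    for k, n_on in enumerate(per_chrom):
        if n_on and config.chrom_length_bp // n_on < need:
            raise ValueError(
                f"cannot pack {n_on} genes with {config.flank} bp flanks on a "
                f"{config.chrom_length_bp} bp chromosome; need >= {n_on * need} bp"
            )
    genes: list[GeneModel] = []
    chrom_sizes: dict[str, int] = {}
    gid = 0
    for k, n_on in enumerate(per_chrom):
        chrom = f"chr{k + 1}"
        chrom_sizes[chrom] = config.chrom_length_bp
        if n_on == 0:
            continue
        slot = config.chrom_length_bp // n_on
        for s in range(n_on):
            length = int(rng.integers(l_min, l_max + 1))
            lo = s * slot + config.flank + margin
            hi = (s + 1) * slot - config.flank - margin - length
            start = int(rng.integers(lo, hi + 1))
            strand = "+" if gid % 2 == 0 else "-"
            n_ex = int(rng.integers(1, 6))
            if n_ex == 1:
                bounds = [0, length]
            else:
                interior = rng.choice(
                    np.arange(1, length), size=2 * n_ex - 2, replace=False
                )
                bounds = [0] + sorted(int(v) for v in interior) + [length]
            exons = tuple(
                GenomicInterval(chrom, start + bounds[2 * e], start + bounds[2 * e + 1], strand)
                for e in range(n_ex)
            )
            genes.append(
                GeneModel(
                    gene_id=f"g{gid:05d}",
                    span=GenomicInterval(chrom, start, start + length, strand),
                    exons=exons,
                )
            )
            gid += 1
    return genes, chrom_sizes


# ------------------------------------------------------------------ expression

@dataclass
class ExpressionTruth:
    truth_tpm: dict[str, float]
    silent_genes: list[str]
    sample_counts: list[dict[str, int]]
    sample_totals: list[int]


def _expression_weights(genes, config: SimulationConfig, rng) -> tuple[dict[str, float], list[str]]:
    n = len(genes)
    n_silent = int(round(config.fraction_silent * n))
    ids = [g.gene_id for g in genes]
    silent = sorted(rng.choice(ids, size=n_silent, replace=False).tolist())
    silent_set = set(silent)
    weights = {}
    for g in ids:
        weights[g] = 0.0 if g in silent_set else float(
            rng.lognormal(config.mu_log, config.sigma_log)
        )
    return weights, silent


def _weights_to_tpm(weights: dict[str, float]) -> dict[str, float]:
    total = sum(weights.values())
    return {g: w / total * 1e6 for g, w in weights.items()}


def _draw_counts(tpm: dict[str, float], depth: int, rng) -> dict[str, int]:
    genes = sorted(tpm)
    p = np.asarray([tpm[g] for g in genes]) / 1e6
    draws = rng.multinomial(depth, p / p.sum())
    return {g: int(c) for g, c in zip(genes, draws) if c > 0}


def simulate_expression(
    genes: list[GeneModel], config: SimulationConfig, n_samples: int = 1
) -> ExpressionTruth:
    """Truth TPM plus per-sample multinomial tag counts (per-sample seeds)."""
    ss = np.random.SeedSequence(config.seed, spawn_key=(1,))
    rng = np.random.default_rng(ss)
    weights, silent = _expression_weights(genes, config, rng)
    tpm = _weights_to_tpm(weights)
    sample_counts, totals = [], []
    for child in ss.spawn(n_samples):
        counts = _draw_counts(tpm, config.depth_tags, np.random.default_rng(child))
        sample_counts.append(counts)
        totals.append(sum(counts.values()))
    return ExpressionTruth(
        truth_tpm=tpm, silent_genes=silent, sample_counts=sample_counts, sample_totals=totals
    )


# ------------------------------------------------------------------ chip reads

def repression_coupling(truth_tpm: dict[str, float]) -> dict[str, float]:
    """r(g) = descending-expression rank fraction (silent genes -> ~1)."""
    genes = sorted(truth_tpm, key=lambda g: (-truth_tpm[g], g))
    n = len(genes)
    if n == 1:
        return {genes[0]: 1.0}
    return {g: i / (n - 1) for i, g in enumerate(genes)}


def _oriented_to_abs(gene: GeneModel, offsets: np.ndarray) -> np.ndarray:
    return gene.tss + offsets if gene.strand == "+" else gene.tss - offsets


def simulate_chip_reads(
    genes: list[GeneModel],
    truth_tpm: dict[str, float],
    config: SimulationConfig,
    chrom_sizes: dict[str, int],
    sample_index: int = 0,
    mark_fold_genes: set[str] | None = None,
) -> tuple[ReadSet, pd.DataFrame]:
    """Draw one ChIP library from the intensity model (module docstring).

    ``mark_fold_genes`` applies the group-B window amplification (factor
    ``config.mark_fold`` over ``config.mark_window``) to those genes.
    Returns the reads plus a per-gene truth table (coupling r, TSS, strand).
    The realized library size is Poisson around ``depth_reads`` (the
    background rate is solved from the expected total intensity, dip
    ignored as a second-order loss).
    """
    ss = np.random.SeedSequence(config.seed, spawn_key=(2, sample_index))
    rng = np.random.default_rng(ss)
    r = repression_coupling(truth_tpm)
    A, B = config.bump_amplitude, config.broad_amplitude
    sigma = config.bump_sigma
    genome_bp = sum(chrom_sizes.values())
    per_gene_extra = A * sigma * SQRT_2PI + B * config.flank
    lam_bg = config.depth_reads / (
        genome_bp + per_gene_extra * sum(r[g.gene_id] for g in genes)
    )
    mark_fold_genes = mark_fold_genes or set()

    chrom_names = sorted(chrom_sizes)
    chrom_index = {c: i for i, c in enumerate(chrom_names)}
    pos_chunks: list[np.ndarray] = []
    code_chunks: list[np.ndarray] = []

    # background: uniform Poisson over each chromosome
    for chrom in chrom_names:
        n_bg = rng.poisson(lam_bg * chrom_sizes[chrom])
        p = rng.integers(0, chrom_sizes[chrom], size=n_bg)
        pos_chunks.append(p)
        code_chunks.append(np.full(n_bg, chrom_index[chrom], dtype=np.int32))

    w0, w1 = config.mark_window
    for g in genes:
        rg = r[g.gene_id]
        if rg == 0:
            continue
        clen = chrom_sizes[g.chrom]
        # promoter bump (Gaussian at bump_center)
        n_bump = rng.poisson(lam_bg * A * rg * sigma * SQRT_2PI)
        off_b = config.bump_center + sigma * rng.standard_normal(n_bump)
        # broad upstream plateau on [-flank, 0)
        n_broad = rng.poisson(lam_bg * B * rg * config.flank)
        off_p = rng.uniform(-config.flank, 0.0, size=n_broad)
        offs = [off_b, off_p]
        if g.gene_id in mark_fold_genes and config.mark_fold != 1.0:
            # extra intensity (f - 1) * lambda(x) restricted to the window
            from scipy.stats import norm

            z0 = (w0 - config.bump_center) / sigma
            z1 = (w1 - config.bump_center) / sigma
            gauss_mass = A * rg * sigma * SQRT_2PI * (norm.cdf(z1) - norm.cdf(z0))
            flat_mass = (1.0 + B * rg) * (w1 - w0)
            extra = (config.mark_fold - 1.0) * lam_bg * (gauss_mass + flat_mass)
            n_extra = rng.poisson(extra)
            p_gauss = gauss_mass / (gauss_mass + flat_mass)
            comp = rng.random(n_extra) < p_gauss
            e_flat = rng.uniform(w0, w1, size=int((~comp).sum()))
            e_gauss = np.empty(int(comp.sum()))
            k = 0
            while k < len(e_gauss):  # rejection-sample the truncated Gaussian
                cand = config.bump_center + sigma * rng.standard_normal(
                    max(16, 2 * (len(e_gauss) - k))
                )
                cand = cand[(cand >= w0) & (cand < w1)]
                take = min(len(cand), len(e_gauss) - k)
                e_gauss[k : k + take] = cand[:take]
                k += take
            offs.extend([e_flat, e_gauss])
        off = np.concatenate(offs) if offs else np.empty(0)
        abs_pos = _oriented_to_abs(g, np.rint(off).astype(np.int64))
        abs_pos = abs_pos[(abs_pos >= 0) & (abs_pos < clen)]
        pos_chunks.append(abs_pos)
        code_chunks.append(np.full(len(abs_pos), chrom_index[g.chrom], dtype=np.int32))

    pos = np.concatenate(pos_chunks)
    codes = np.concatenate(code_chunks)

    # TSS nucleosome-depletion dip: thin reads near every TSS
    d, w = config.tss_dip_depth, config.tss_dip_width
    if d > 0:
        order = np.lexsort((pos, codes))
        pos, codes = pos[order], codes[order]
        keep = np.ones(len(pos), dtype=bool)
        reach = int(5 * w)
        for g in genes:
            ci = chrom_index[g.chrom]
            base = np.searchsorted(codes, ci, side="left")
            stop = np.searchsorted(codes, ci, side="right")
            lo = base + np.searchsorted(pos[base:stop], g.tss - reach)
            hi = base + np.searchsorted(pos[base:stop], g.tss + reach + 1)
            if hi > lo:
                x = pos[lo:hi] - g.tss
                p_drop = d * np.exp(-(x.astype(float) ** 2) / (2 * w * w))
                keep[lo:hi] = rng.random(hi - lo) >= p_drop
        pos, codes = pos[keep], codes[keep]

    # clip so BED round-trips cleanly for either strand
    L = config.read_length
    ok = (pos >= L - 1) & (pos < max(chrom_sizes.values()) - L)
    pos, codes = pos[ok], codes[ok]
    strands = np.random.default_rng(ss.spawn(1)[0]).random(len(pos)) < 0.5
    order = np.lexsort((pos, codes))
    reads = ReadSet(chrom_names, codes[order], pos[order], strands[order], length=L)

    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "r": [r[g.gene_id] for g in genes],
            "tss": [g.tss for g in genes],
            "strand": [g.strand for g in genes],
            "tpm": [truth_tpm[g.gene_id] for g in genes],
        }
    )
    return reads, truth


def simulate_peaks(
    genes: list[GeneModel],
    truth_tpm: dict[str, float],
    config: SimulationConfig,
    top_fraction: float = 0.15,
) -> list[Peak]:
    """Deterministic promoter peaks at the most-repressed genes.

    A convenience for end-to-end runs (peak calling itself is upstream of
    this package): the ``top_fraction`` genes by repression coupling get a
    peak spanning oriented offsets [-3000, -1000) with its summit at the
    planted bump centre.
    """
    r = repression_coupling(truth_tpm)
    ranked = sorted(genes, key=lambda g: (-r[g.gene_id], g.gene_id))
    n_peaks = max(1, int(round(top_fraction * len(genes))))
    peaks = []
    for g in ranked[:n_peaks]:
        lo_off, hi_off = -3000, -1000
        a = _oriented_to_abs(g, np.asarray([lo_off, hi_off - 1]))
        start, end = int(min(a)), int(max(a)) + 1
        summit = int(_oriented_to_abs(g, np.asarray([config.bump_center]))[0])
        peaks.append(
            Peak(
                interval=GenomicInterval(g.chrom, start, end),
                summit=summit,
                p_value=100.0,
                fold_enrichment=1.0 + config.bump_amplitude * r[g.gene_id],
                name=f"peak_{g.gene_id}",
            )
        )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


# ---------------------------------------------------------------- two groups

@dataclass
class TwoGroupStudy:
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    truth_tpm_a: dict[str, float]
    truth_tpm_b: dict[str, float]
    affected_genes: list[str]
    tag_counts: dict[str, list[dict[str, int]]]  # group -> per-sample counts
    tag_totals: dict[str, list[int]]
    reads: dict[str, list[ReadSet]]  # group -> per-sample reads


def simulate_two_group_study(config: SimulationConfig, chip: bool = True) -> TwoGroupStudy:
    """Two-group design: expression down / promoter mark up in group B.

    Affected genes are the ``n_affected`` genes ranked immediately above the
    median expressed gene (a homogeneous, well-detectable band).  Group B
    multiplies their expression weight by ``2^-expr_delta`` (renormalized)
    and their ChIP intensity over ``mark_window`` by ``mark_fold``.  Every
    sample has its own seed stream; the repression coupling r(g) is shared
    (it reflects the baseline biology, not the group contrast).
    """
    genes, chrom_sizes = simulate_gene_models(config)
    ss = np.random.SeedSequence(config.seed, spawn_key=(3,))
    rng = np.random.default_rng(ss)
    weights, silent = _expression_weights(genes, config, rng)
    tpm_a = _weights_to_tpm(weights)

    expressed = sorted(
        (g for g in weights if weights[g] > 0), key=lambda g: (-weights[g], g)
    )
    if config.n_affected > len(expressed):
        raise ValueError("n_affected exceeds the number of expressed genes")
    mid = len(expressed) // 2
    lo = max(0, mid - config.n_affected)
    affected = sorted(expressed[lo:mid])

    weights_b = dict(weights)
    for g in affected:
        weights_b[g] = weights[g] * 2.0 ** (-config.expr_delta)
    tpm_b = _weights_to_tpm(weights_b)

    tag_counts: dict[str, list[dict[str, int]]] = {"A": [], "B": []}
    tag_totals: dict[str, list[int]] = {"A": [], "B": []}
    reads: dict[str, list[ReadSet]] = {"A": [], "B": []}
    n_per = config.n_samples_per_group
    children = ss.spawn(2 * n_per)
    for s in range(n_per):
        counts = _draw_counts(tpm_a, config.depth_tags, np.random.default_rng(children[s]))
        tag_counts["A"].append(counts)
        tag_totals["A"].append(sum(counts.values()))
        if chip:
            rd, _ = simulate_chip_reads(
                genes, tpm_a, config, chrom_sizes, sample_index=10 + s
            )
            reads["A"].append(rd)
    for s in range(n_per):
        counts = _draw_counts(tpm_b, config.depth_tags, np.random.default_rng(children[n_per + s]))
        tag_counts["B"].append(counts)
        tag_totals["B"].append(sum(counts.values()))
        if chip:
            rd, _ = simulate_chip_reads(
                genes,
                tpm_a,  # shared coupling; the group effect is the explicit window fold
                config,
                chrom_sizes,
                sample_index=20 + s,
                mark_fold_genes=set(affected),
            )
            reads["B"].append(rd)

    return TwoGroupStudy(
        genes=genes,
        chrom_sizes=chrom_sizes,
        truth_tpm_a=tpm_a,
        truth_tpm_b=tpm_b,
        affected_genes=affected,
        tag_counts=tag_counts,
        tag_totals=tag_totals,
        reads=reads,
    )
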