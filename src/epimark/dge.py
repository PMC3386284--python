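"""Digital gene expression: tag extraction, mapping, TPM, strata, DE.

The DGE chemistry is NlaIII/MmeI tag profiling: NlaIII cuts cDNA at CATG
sites, MmeI cuts 17 bp downstream, so a tag is the 21-mer ``CATG`` + 17 bp.
The canonical tag of a transcript is its 3'-most CATG site with >= 17 bp
downstream.  Observed tags are mapped allowing at most one mismatch, exact
matches taking precedence, and are counted only when they identify exactly
one gene ("unambiguous").  Expression is normalized to TPM: tag count /
total clean tags x 10^6.

Two-library differential expression uses the exact two-library count test:
under the equal-proportion null, conditional on the pair total n = x + y,
the first library's count is Binomial(n, N1/(N1+N2)); the two-sided p-value
sums all outcomes no more likely than the observed one (the minimum-
likelihood exact method), which makes the test exactly symmetric under
swapping the libraries.  This is the conditional form of the classic
two-library Poisson (Audic-Claverie) test.  Genes are called significant
under the joint rule FDR <= 0.01 (Benjamini-Hochberg) and |log2Ratio| >= 1,
with a 0.5 pseudocount in the ratio only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DgeTag",
    "DifferentialExpressionResult",
    "extract_tags",
    "build_tag_reference",
    "map_tags_to_genes",
    "tpm_normalize",
    "stratify_by_expression",
    "pick_strata",
    "differential_expression",
]

TAG_LENGTH = 21
_ANCHOR = "CATG"


@dataclass(frozen=True)
class DgeTag:
    """A 21 bp CATG-anchored expression tag."""

    sequence: str
    source_gene: str = ""
    site_rank: int = 1  # 1 = 3'-most qualifying CATG site

    def __post_init__(self) -> None:
        if len(self.sequence) != TAG_LENGTH:
            raise ValueError(f"tag must be {TAG_LENGTH} bp")
        if not self.sequence.startswith(_ANCHOR):
            raise ValueError("tag must start with CATG")


@dataclass(frozen=True)
class DifferentialExpressionResult:
    gene_id: str
    log2_ratio: float
    p_value: float
    fdr: float
    significant: bool
    count_a: int
    count_b: int


def extract_tags(
    transcript: str, mode: str = "three_prime_most", source_gene: str = ""
) -> list[DgeTag]:
    """Extract CATG-anchored 21 bp tags from a transcript sequence.

    A site qualifies when at least 17 bp follow the CATG.  Mode
    ``three_prime_most`` emits only the 3'-most qualifying site (the
    canonical tag); mode ``all`` emits every qualifying site with its rank
    counted from the 3' end (rank 1 = 3'-most).
    """
    if mode not in ("three_prime_most", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    seq = transcript.upper()
    sites = []
    i = seq.find(_ANCHOR)
    while i != -1:
        if i + TAG_LENGTH <= len(seq):
            sites.append(i)
        i = seq.find(_ANCHOR, i + 1)
    if not sites:
        return []
    sites.sort(reverse=True)  # 3'-most first
    if mode == "three_prime_most":
        sites = sites[:1]
    return [
        DgeTag(seq[s : s + TAG_LENGTH], source_gene=source_gene, site_rank=rank)
        for rank, s in enumerate(sites, start=1)
    ]


def build_tag_reference(
    transcripts: dict[str, str], mode: str = "three_prime_most"
) -> dict[str, set[str]]:
    """{gene_id: set of tag sequences} from transcript sequences."""
    return {
        gid: {t.sequence for t in extract_tags(seq, mode=mode, source_gene=gid)}
        for gid, seq in transcripts.items()
    }


def _variants(tag: str):
    for i, base in enumerate(tag):
        for b in "ACGT":
            if b != base:
                yield tag[:i] + b + tag[i + 1 :]


def map_tags_to_genes(
    observed_tags: list[str],
    reference: dict[str, set[str]],
    max_mismatch: int = 1,
) -> tuple[dict[str, int], int, int]:
    """Count observed tags per gene under best-tier unambiguous mapping.

    A tag maps at the best available tier (exact before 1-mismatch) and is
    counted only if it hits exactly one gene at that tier; otherwise it is
    tallied ambiguous (>= 2 genes) or unmapped (no gene at distance <=
    ``max_mismatch``, or a non-ACGT character).  Returns
    ``(counts, n_ambiguous, n_unmapped)``.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    exact: dict[str, set[str]] = {}
    for gid, tags in reference.items():
        for t in tags:
            exact.setdefault(t, set()).add(gid)

    counts: dict[str, int] = {}
    n_ambiguous = n_unmapped = 0
    valid = set("ACGT")
    for tag in observed_tags:
        tag = tag.upper()
        if len(tag) != TAG_LENGTH or not set(tag) <= valid:
            n_unmapped += 1
            continue
        genes = exact.get(tag, set())
        if not genes and max_mismatch >= 1:
            genes = set()
            for v in _variants(tag):
                genes |= exact.get(v, set())
        if len(genes) == 1:
            gid = next(iter(genes))
            counts[gid] = counts.get(gid, 0) + 1
        elif len(genes) > 1:
            n_ambiguous += 1
        else:
            n_unmapped += 1
    return counts, n_ambiguous, n_unmapped


def tpm_normalize(counts: dict[str, int], total_clean_tags: int) -> dict[str, float]:
    """TPM(g) = count(g) / total clean tags x 10^6."""
    if total_clean_tags <= 0:
        raise ValueError("total_clean_tags must be > 0")
    return {g: c / total_clean_tags * 1e6 for g, c in counts.items()}


def stratify_by_expression(tpm: dict[str, float], n_sets: int = 10) -> list[list[str]]:
    """Rank genes by TPM (descending, ties broken by gene_id) into equal sets.

    Set sizes are ``n // n_sets`` with the remainder going to the last set;
    set 0 holds the most highly expressed genes.
    """
    if n_sets < 2:
        raise ValueError("n_sets must be >= 2")
    genes = sorted(tpm, key=lambda g: (-tpm[g], g))
    if len(genes) < n_sets:
        raise ValueError("fewer genes than sets")
    size = len(genes) // n_sets
    sets = [genes[i * size : (i + 1) * size] for i in range(n_sets - 1)]
    sets.append(genes[(n_sets - 1) * size :])
    return sets


DEFAULT_PICK = {"high": 0, "medium": 3, "low": 6, "silent": 9}


def pick_strata(
    sets: list[list[str]],
    mapping: dict[str, int] | None = None,
    silent_by_zero_tpm: dict[str, float] | None = None,
) -> dict[str, list[str]]:
    """Select named strata out of the ranked sets.

    Default mapping: high -> set 0, medium -> set 3, low -> set 6,
    silent -> last set.  Passing ``silent_by_zero_tpm`` (a TPM table)
    redefines the silent stratum as the genes with TPM == 0 instead.
    """
    mapping = dict(DEFAULT_PICK if mapping is None else mapping)
    if "silent" in mapping and mapping["silent"] >= len(sets):
        mapping["silent"] = len(sets) - 1
    out = {name: list(sets[idx]) for name, idx in mapping.items()}
    if silent_by_zero_tpm is not None and "silent" in out:
        out["silent"] = sorted(g for g, v in silent_by_zero_tpm.items() if v == 0.0)
    return out


def _binom_two_sided(x: np.ndarray, n: np.ndarray, p: float) -> np.ndarray:
    """Vectorized exact two-sided binomial p-values (minimum-likelihood).

    The two-sided set {k : P(k) <= P(x)} of a unimodal pmf is a union of
    two tails; the opposite-tail boundary is found by bisection on the
    monotone side.  Matches scipy.stats.binomtest to float precision
    (cross-checked in the test suite).
    """
    x = np.asarray(x, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    pval = np.ones(x.shape, dtype=float)
    pos = n > 0
    if not pos.any():
        return pval
    x, n_ = x[pos], n[pos]
    # R/scipy-style relative slack so float noise cannot drop a tied outcome
    thresh = binom.logpmf(x, n_, p) + 1e-7
    mode = np.clip(np.floor((n_ + 1) * p).astype(np.int64), 0, n_)
    left = x <= mode
    n_iter = int(np.ceil(np.log2(float(n_.max()) + 2.0))) + 2

    def _pmf_ok(k: np.ndarray) -> np.ndarray:
        inside = (k >= 0) & (k <= n_)
        val = binom.logpmf(np.clip(k, 0, n_), n_, p)
        return np.where(inside, val, -np.inf) <= thresh

    # b = smallest k in [mode, n+1] with pmf(k) <= pmf(x) (pmf falls past mode)
    lo, hi = mode.copy(), n_ + 1
    for _ in range(n_iter):
        mid = (lo + hi) // 2
        ok = _pmf_ok(mid)
        hi = np.where(ok, mid, hi)
        lo = np.where(ok, lo, mid + 1)
    b = hi
    # a = largest k in [-1, mode] with pmf(k) <= pmf(x) (pmf rises to mode)
    lo, hi = np.full_like(mode, -1), mode.copy()
    for _ in range(n_iter):
        mid = (lo + hi + 1) // 2
        ok = _pmf_ok(mid)
        lo = np.where(ok, mid, lo)
        hi = np.where(ok, hi, mid - 1)
    a = lo

    p_left_case = binom.cdf(x, n_, p) + binom.sf(b - 1, n_, p)  # sf(n)=0 when b=n+1
    p_right_case = binom.sf(x - 1, n_, p) + np.where(a >= 0, binom.cdf(np.maximum(a, 0), n_, p), 0.0)
    pval[pos] = np.minimum(np.where(left, p_left_case, p_right_case), 1.0)
    return pval


def differential_expression(
    counts_a: dict[str, int],
    total_a: int,
    counts_b: dict[str, int],
    total_b: int,
    fdr_threshold: float = 0.01,
    lfc_threshold: float = 1.0,
) -> list[DifferentialExpressionResult]:
    """Exact two-library DE test over the union of genes (see module doc).

    ``log2_ratio`` is log2 of the (A over B) proportion ratio with a 0.5
    pseudocount on each count; significance additionally requires the
    count-based BH-adjusted p-value.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be > 0")
    genes = sorted(set(counts_a) | set(counts_b))
    x = np.asarray([counts_a.get(g, 0) for g in genes], dtype=np.int64)
    y = np.asarray([counts_b.get(g, 0) for g in genes], dtype=np.int64)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative counts")
    n = x + y
    p_null = total_a / (total_a + total_b)
    pvals = _binom_two_sided(x, n, p_null)
    lfc = np.log2(((x + 0.5) / total_a) / ((y + 0.5) / total_b))
    if len(genes):
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        fdr = np.empty(0)
    sig = (fdr <= fdr_threshold) & (np.abs(lfc) >= lfc_threshold)
    return [
        DifferentialExpressionResult(
            gene_id=g,
            log2_ratio=float(lfc[i]),
            p_value=float(pvals[i]),
            fdr=float(fdr[i]),
            significant=bool(sig[i]),
            count_a=int(x[i]),
            count_b=int(y[i]),
        )
        for i, g in enumerate(genes)
    ]
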