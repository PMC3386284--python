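"""Integration of ChIP profiles with expression: strata curves, concordance
calls, and Spearman-centroid hierarchical clustering.

Concordance calls contrast a gene's expression class with its promoter
mark class, both by quantile cuts (default 25%/75%): high expression with a
high repressive mark is *co-expressed* (the mark failed to silence), low
with low is *co-suppressed*; the expected, mark-consistent quadrants are
*expressed_consistent* (high expression, low mark) and
*repressed_consistent* (low expression, high mark).  Genes between the
cuts stay uncalled.

The clustering pins one specific convention, since "centroid" linkage on a
non-Euclidean correlation distance is convention-dependent: every row is
rank-transformed once up front, a cluster's centroid is the element-wise
mean of its members' rank vectors, and the distance between clusters is 1
minus the Pearson correlation of those centroids (for singletons this is
exactly 1 minus the Spearman correlation, and the whole dendrogram is
invariant to monotone transformations of any row).  Ties in the merge
order are broken by the lexicographically smallest pair of cluster
representatives (a cluster's representative is its smallest member label),
which makes the dendrogram deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import GeneModel, ReadSet
from .profiles import aggregate_density, metagene_profile, promoter_window_densities, tss_profile_matrix

log = logging.getLogger(__name__)

__all__ = [
    "ConcordanceCall",
    "ClusterResult",
    "stratified_profiles",
    "classify_concordance",
    "spearman_centroid_cluster",
    "spearman_distance_matrix",
]


@dataclass(frozen=True)
class ConcordanceCall:
    gene_id: str
    expression_class: str  # "high" | "low"
    mark_class: str  # "high" | "low"
    call: str

    def __post_init__(self) -> None:
        expected = {
            ("high", "high"): "co_expressed",
            ("low", "low"): "co_suppressed",
            ("high", "low"): "expressed_consistent",
            ("low", "high"): "repressed_consistent",
        }[(self.expression_class, self.mark_class)]
        if self.call != expected:
            raise ValueError("inconsistent concordance call")


def stratified_profiles(
    reads: ReadSet,
    genes: list[GeneModel],
    strata: dict[str, list[str]],
    geometry: str = "tss",
    genome_sizes: dict[str, int] | None = None,
    **kwargs,
):
    """One aggregate density curve per stratum.

    Returns ``(col_labels, {stratum: curve})``.  Strata must be disjoint,
    non-empty subsets of the gene list.
    """
    seen: set[str] = set()
    for name, ids in strata.items():
        if not ids:
            raise ValueError(f"stratum {name!r} is empty")
        overlap = seen & set(ids)
        if overlap:
            raise ValueError(f"strata overlap on {sorted(overlap)[:3]} ...")
        seen |= set(ids)

    builder = {
        "tss": tss_profile_matrix,
        "metagene": metagene_profile,
        "promoter": promoter_window_densities,
    }[geometry]
    matrix = builder(reads, genes, genome_sizes=genome_sizes, **kwargs)
    curves = {name: aggregate_density(matrix, ids) for name, ids in strata.items()}
    return matrix.col_labels if matrix.col_offsets is None else matrix.col_offsets, curves


def classify_concordance(
    tpm: dict[str, float],
    promoter_density: dict[str, float],
    expr_quantiles: tuple[float, float] = (0.25, 0.75),
    mark_quantiles: tuple[float, float] = (0.25, 0.75),
) -> list[ConcordanceCall]:
    """Quantile-based concordance calls on a shared gene universe."""
    if set(tpm) != set(promoter_density):
        raise ValueError("tpm and promoter_density must cover the same genes")
    genes = sorted(tpm)
    ev = np.asarray([tpm[g] for g in genes], dtype=float)
    mv = np.asarray([promoter_density[g] for g in genes], dtype=float)

    def cuts(v, q):
        lo, hi = np.quantile(v, q[0]), np.quantile(v, q[1])
        if lo == hi:
            log.warning("degenerate distribution: all values between cuts; no calls")
            return None
        return lo, hi

    ec = cuts(ev, expr_quantiles)
    mc = cuts(mv, mark_quantiles)
    if ec is None or mc is None:
        return []

    call_map = {
        ("high", "high"): "co_expressed",
        ("low", "low"): "co_suppressed",
        ("high", "low"): "expressed_consistent",
        ("low", "high"): "repressed_consistent",
    }
    out = []
    for g, e, m in zip(genes, ev, mv):
        e_cls = "low" if e <= ec[0] else ("high" if e >= ec[1] else None)
        m_cls = "low" if m <= mc[0] else ("high" if m >= mc[1] else None)
        if e_cls is None or m_cls is None:
            continue
        out.append(
            ConcordanceCall(
                gene_id=g,
                expression_class=e_cls,
                mark_class=m_cls,
                call=call_map[(e_cls, m_cls)],
            )
        )
    return out


# ------------------------------------------------------------------ clustering

@dataclass
class ClusterResult:
    labels: list[str]
    merges: list[tuple[int, int, float, int]]  # (id_a, id_b, height, new_id)
    leaf_order: list[str]
    dropped: list[str]


def spearman_distance_matrix(matrix: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Spearman distances between rows (symmetric, zero diag,
    range [0, 2])."""
    ranks = np.apply_along_axis(rankdata, 1, np.asarray(matrix, dtype=float))
    c = np.corrcoef(ranks)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _centroid_dist(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Pearson correlation of rank centroids.

    A merged centroid can become constant (e.g. the mean of two mirrored
    rank rows); its correlation is undefined and is pinned to 0
    (distance 1).
    """
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 1.0
    return float(1.0 - np.corrcoef(a, b)[0, 1])


def spearman_centroid_cluster(matrix, labels: list[str] | None = None) -> ClusterResult:
    """Agglomerative centroid clustering under 1 - Spearman distance.

    ``matrix`` is genes x features (DataFrame or array).  Constant rows have
    undefined rank correlation and are dropped with a warning.  See the
    module docstring for the pinned centroid convention and tie-break.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = [str(i) for i in matrix.index]
        data = matrix.to_numpy(dtype=float)
    else:
        data = np.asarray(matrix, dtype=float)
        if labels is None:
            labels = [f"row{i}" for i in range(data.shape[0])]
    if np.isnan(data).any():
        raise ValueError("missing values not allowed")
    keep = [i for i in range(data.shape[0]) if np.ptp(data[i]) > 0]
    dropped = [labels[i] for i in range(data.shape[0]) if i not in set(keep)]
    if dropped:
        log.warning("dropping %d constant rows: %s", len(dropped), dropped[:5])
    data = data[keep]
    labels = [labels[i] for i in keep]
    n = data.shape[0]
    if n < 2 or data.shape[1] < 2:
        raise ValueError("need >= 2 non-constant rows and >= 2 features")
    data = np.apply_along_axis(rankdata, 1, data)  # Spearman = Pearson on ranks

    # active clusters: id -> (centroid, representative label, member leaf ids)
    centroids = {i: data[i].copy() for i in range(n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    rep = {i: labels[i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    active = set(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = _centroid_dist(centroids[i], centroids[j])

    merges: list[tuple[int, int, float, int]] = []
    tree: dict[int, tuple[int, int]] = {}
    next_id = n
    while len(active) > 1:
        # deterministic argmin: smallest distance, ties by representative pair
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], *sorted((rep[kv[0][0]], rep[kv[0][1]]))),
        )
        (i, j), h = best
        new = next_id
        next_id += 1
        leaf_ids = members[i] + members[j]
        centroids[new] = data[leaf_ids].mean(axis=0)
        members[new] = leaf_ids
        rep[new] = min(rep[i], rep[j])
        tree[new] = (i, j)
        merges.append((i, j, h, new))
        active -= {i, j}
        for k in (i, j):
            for key in [key for key in dist if k in key]:
                del dist[key]
        for k in active:
            a, b = (k, new) if k < new else (new, k)
            dist[(a, b)] = _centroid_dist(centroids[k], centroids[new])
        active.add(new)

    def order(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = tree[node]
        if rep[a] > rep[b]:
            a, b = b, a
        return order(a) + order(b)

    root = next_id - 1 if merges else 0
    leaf_order = [labels[i] for i in order(root)] if n > 1 else labels[:]
    return ClusterResult(labels=labels, merges=merges, leaf_order=leaf_order, dropped=dropped)
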