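"""Promoter-window differential modification test between two sample groups.

For a chosen gene set, each gene contributes a 10-vector of tag densities
over the 500 bp windows tiling [-5000, 0) upstream of its TSS, per group
(samples within a group are library-size scaled and averaged).  Each window
is then tested across genes for a group difference.

Because the *same* genes constitute both groups, gene identity is a shared
blocking factor: an unpaired test absorbs the (large) between-gene density
variation into its error term and becomes structurally conservative.  The
default is therefore a paired t-test on the per-gene A - B differences;
Welch's unpaired two-sample test is available via ``method="welch"`` for
comparison.  Windows are flagged at raw two-sided P < 0.05 (no multiplicity
correction by default; Benjamini-Hochberg available via ``correct="bh"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["WindowComparisonResult", "compare_promoter_windows"]


@dataclass(frozen=True)
class WindowComparisonResult:
    window: tuple[int, int]  # oriented offset interval, e.g. (-2000, -1500)
    mean_density_a: float
    mean_density_b: float
    t_statistic: float
    p_value: float
    flagged: bool
    degenerate: bool = False


def compare_promoter_windows(
    densities_a: np.ndarray,
    densities_b: np.ndarray,
    window: int = 500,
    span: int = 5_000,
    alpha: float = 0.05,
    method: str = "paired",
    correct: str | None = None,
) -> list[WindowComparisonResult]:
    """Per-window t-tests of group A vs group B per-gene densities.

    ``densities_a``/``densities_b`` are genes x windows arrays on the same
    gene set and geometry (rows aligned gene-for-gene).  Requires >= 3
    genes.  Windows with zero variance in both groups are reported with
    t = 0, p = 1 and the ``degenerate`` flag.
    """
    a = np.asarray(densities_a, dtype=float)
    b = np.asarray(densities_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("group density matrices must have identical shape")
    n_genes, n_win = a.shape
    if n_genes < 3:
        raise ValueError("need at least 3 genes")
    if n_win * window != span:
        raise ValueError(f"expected {span // window} windows of {window} bp")
    if method not in ("paired", "welch"):
        raise ValueError(f"unknown method {method!r}")

    edges = [(-span + j * window, -span + (j + 1) * window) for j in range(n_win)]
    tstats = np.zeros(n_win)
    pvals = np.ones(n_win)
    degenerate = np.zeros(n_win, dtype=bool)
    for j in range(n_win):
        av, bv = a[:, j], b[:, j]
        if np.ptp(av) == 0 and np.ptp(bv) == 0:
            degenerate[j] = True
            if not np.allclose(av.mean(), bv.mean()):
                # constant but different: infinitely strong evidence
                tstats[j], pvals[j] = np.inf * np.sign(av.mean() - bv.mean()), 0.0
            continue
        if method == "paired":
            diff = av - bv
            if np.ptp(diff) == 0:
                degenerate[j] = True
                if diff[0] != 0:
                    tstats[j], pvals[j] = np.inf * np.sign(diff[0]), 0.0
                continue
            res = stats.ttest_rel(av, bv)
        else:
            res = stats.ttest_ind(av, bv, equal_var=False)
        tstats[j], pvals[j] = float(res.statistic), float(res.pvalue)

    if correct == "bh":
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
        flagged = p_adj < alpha
    elif correct is None:
        flagged = pvals < alpha
    else:
        raise ValueError(f"unknown correction {correct!r}")

    return [
        WindowComparisonResult(
            window=edges[j],
            mean_density_a=float(a[:, j].mean()),
            mean_density_b=float(b[:, j].mean()),
            t_statistic=float(tstats[j]),
            p_value=float(pvals[j]),
            flagged=bool(flagged[j]),
            degenerate=bool(degenerate[j]),
        )
        for j in range(n_win)
    ]
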