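"""ChIP-qPCR arithmetic: standard-curve primer efficiency and 2^-ddCp folds.

A primer pair's amplification efficiency comes from a dilution-series
standard curve: regress Cp on log10(template ng); a perfectly doubling
reaction has slope -1/log10(2) = -3.3219 and efficiency
10^(-1/slope) = 2.  Relative enrichment at a target site is the
difference-of-differences of crossing points — ChIP vs input, target
primer vs negative-control primer — folded through base 2:
fold = 2^-((Cp_chip,target - Cp_input,target) - (Cp_chip,neg - Cp_input,neg)).
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["StandardCurve", "standard_curve_efficiency", "ddcp_fold_enrichment", "mean_cp"]


@dataclass(frozen=True)
class StandardCurve:
    points: tuple[tuple[float, float], ...]  # (log10 input ng, Cp)
    slope: float
    intercept: float
    efficiency: float  # amplification factor per cycle
    r_squared: float


def standard_curve_efficiency(points) -> StandardCurve:
    """Least-squares Cp vs log10(ng) line and per-cycle efficiency.

    ``points`` is an iterable of (log10 input ng, Cp) pairs at >= 3 distinct
    concentrations.  A non-negative slope means the reaction did not
    amplify and is an error.
    """
    pts = tuple((float(x), float(y)) for x, y in points)
    xs = np.asarray([p[0] for p in pts])
    ys = np.asarray([p[1] for p in pts])
    if len(set(xs)) < 3:
        raise ValueError("need >= 3 distinct concentrations")
    fit = stats.linregress(xs, ys)
    if fit.slope >= 0:
        raise ValueError("non-amplifying reaction: standard-curve slope >= 0")
    return StandardCurve(
        points=pts,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(10.0 ** (-1.0 / fit.slope)),
        r_squared=float(fit.rvalue**2),
    )


def mean_cp(cps) -> tuple[float, float]:
    """Mean and SD of replicate Cp values (replicates averaged before ddCp)."""
    arr = np.asarray(list(cps), dtype=float)
    if arr.size == 0:
        raise ValueError("no Cp values")
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def ddcp_fold_enrichment(
    cp_chip_target: float,
    cp_input_target: float,
    cp_chip_negative: float,
    cp_input_negative: float,
) -> float:
    """2^-ddCp relative enrichment of a target site over a negative site."""
    for cp in (cp_chip_target, cp_input_target, cp_chip_negative, cp_input_negative):
        if cp <= 0:
            raise ValueError("Cp values must be > 0")
    d_target = cp_chip_target - cp_input_target
    d_negative = cp_chip_negative - cp_input_negative
    return float(2.0 ** -(d_target - d_negative))
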