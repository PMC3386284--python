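"""Interval-set algebra on sorted, merged (starts, ends) array pairs.

An *interval set* is a pair of equal-length int64 arrays ``(starts, ends)``
with ``starts`` strictly increasing and ``ends[i] <= starts[i+1]`` (disjoint,
sorted, half-open).  These primitives back the genome partition, the peak
association sweep and the saturation-curve density, so they are written and
tested against per-base-pair brute force.
"""

from __future__ import annotations

import numpy as np

IntervalSet = tuple[np.ndarray, np.ndarray]

EMPTY: IntervalSet = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))


def make(pairs) -> IntervalSet:
    """Merge arbitrary (start, end) pairs into a canonical interval set."""
    pairs = [(int(s), int(e)) for s, e in pairs if e > s]
    if not pairs:
        return EMPTY
    pairs.sort()
    starts, ends = [], []
    cs, ce = pairs[0]
    for s, e in pairs[1:]:
        if s <= ce:  # touching intervals merge too
            ce = max(ce, e)
        else:
            starts.append(cs)
            ends.append(ce)
            cs, ce = s, e
    starts.append(cs)
    ends.append(ce)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def total_length(a: IntervalSet) -> int:
    return int((a[1] - a[0]).sum())


def union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return make(list(zip(a[0], a[1])) + list(zip(b[0], b[1])))


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Set difference a \\ b."""
    out = []
    bs, be = b
    for s, e in zip(a[0], a[1]):
        cur = int(s)
        # b-intervals that can intersect [s, e)
        i = int(np.searchsorted(be, s, side="right"))
        while i < len(bs) and bs[i] < e:
            if bs[i] > cur:
                out.append((cur, int(bs[i])))
            cur = max(cur, int(be[i]))
            i += 1
        if cur < e:
            out.append((cur, int(e)))
    return make(out)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    out = []
    bs, be = b
    for s, e in zip(a[0], a[1]):
        i = int(np.searchsorted(be, s, side="right"))
        while i < len(bs) and bs[i] < e:
            out.append((max(int(s), int(bs[i])), min(int(e), int(be[i]))))
            i += 1
    return make(out)


def contains(a: IntervalSet, pos: np.ndarray) -> np.ndarray:
    """Boolean membership of each position in the interval set."""
    pos = np.asarray(pos, dtype=np.int64)
    starts, ends = a
    if len(starts) == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(pos.shape, dtype=bool)
    hit[ok] = pos[ok] < ends[idx[ok]]
    return hit


def count_in(a: IntervalSet, sorted_pos: np.ndarray) -> int:
    """Number of sorted positions falling inside the set (binary search)."""
    starts, ends = a
    lo = np.searchsorted(sorted_pos, starts, side="left")
    hi = np.searchsorted(sorted_pos, ends, side="left")
    return int((hi - lo).sum())


def clip(a: IntervalSet, lo: int, hi: int) -> IntervalSet:
    return intersect(a, make([(lo, hi)]))
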