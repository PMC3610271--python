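"""Minimal half-open interval arithmetic on a single chromosome.

All intervals are 0-based half-open [start, end) and represented as two
parallel integer arrays.  These three primitives (merge, subtract, point
membership) are all the compartment partition, repeat masks and LAD
handling need.
"""

from __future__ import annotations

import numpy as np


def merge(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals as a sorted, disjoint set."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def subtract(starts_a, ends_a, starts_b, ends_b) -> tuple[np.ndarray, np.ndarray]:
    """Set difference A \\ B.  Both inputs may be unmerged."""
    sa, ea = merge(starts_a, ends_a)
    sb, eb = merge(starts_b, ends_b)
    if sa.size == 0 or sb.size == 0:
        return sa, ea
    out_s, out_e = [], []
    j = 0
    for s, e in zip(sa, ea):
        cur = s
        while j < sb.size and eb[j] <= cur:
            j += 1
        k = j
        while k < sb.size and sb[k] < e:
            if sb[k] > cur:
                out_s.append(cur)
                out_e.append(sb[k])
            cur = max(cur, eb[k])
            if eb[k] >= e:
                break
            k += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def total_length(starts, ends) -> int:
    s, e = merge(starts, ends)
    return int((e - s).sum())


def contains(starts, ends, points) -> np.ndarray:
    """Boolean mask: is each point inside the union of the intervals?"""
    s, e = merge(starts, ends)
    points = np.asarray(points, dtype=np.int64)
    if s.size == 0:
        return np.zeros(points.shape, dtype=bool)
    idx = np.searchsorted(s, points, side="right") - 1
    ok = idx >= 0
    out = np.zeros(points.shape, dtype=bool)
    out[ok] = points[ok] < e[idx[ok]]
    return out
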