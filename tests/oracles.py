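"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive each result by the most direct method
available (explicit enumeration, per-window rescoring, naive summation) so
that agreement with the package's optimized implementations is meaningful.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


# --- peak calling ----------------------------------------------------------

def peaks_bruteforce(pos, cnt, window, threshold, vicinity):
    """Enumerate every tag-anchored window by double loop, then apply the
    same greedy highest-count-first / leftmost suppression."""
    pos = np.asarray(pos)
    cnt = np.asarray(cnt)
    cands = []
    for i, p in enumerate(pos):
        total = 0
        for q, c in zip(pos, cnt):
            if p <= q < p + window:
                total += c
        if total >= threshold:
            cands.append((int(p), int(total)))
    cands.sort(key=lambda pc: (-pc[1], pc[0]))
    accepted = []
    for p, c in cands:
        center = p + window // 2
        if all(abs(center - a[0]) >= vicinity for a in accepted):
            accepted.append((center, c))
    return sorted(accepted)


# --- segmentation ----------------------------------------------------------

def segment_score(pos, cnt, i, j, d, P):
    return float(cnt[i:j + 1].sum() - d * (pos[j] + 1 - pos[i]) - 2.0 * P)


def partition_recursive(pos, cnt, d, P):
    """Exhaustive search over all disjoint rich-segment sets via memoized
    recursion; returns (best score, segments as (start_idx, end_idx) list).

    Tie-breaks match the production DP: prefer not opening a segment, and
    prefer the shortest (latest-starting) segment otherwise.
    """
    pos = np.asarray(pos)
    cnt = np.asarray(cnt, dtype=float)
    n = pos.size

    @lru_cache(maxsize=None)
    def best(j):
        # best over tags 0..j inclusive
        if j < 0:
            return 0.0, ()
        sc_skip, segs_skip = best(j - 1)
        out = (sc_skip, segs_skip)
        for i in range(j, -1, -1):   # latest start first: shorter wins ties
            prev_sc, prev_segs = best(i - 1)
            sc = prev_sc + segment_score(pos, cnt, i, j, d, P)
            if sc > out[0]:
                out = (sc, prev_segs + ((i, j),))
        return out

    score, segs = best(n - 1)
    return score, list(segs)


def all_interval_sets(n):
    """Every set of disjoint index intervals over 0..n-1 (full enumeration)."""
    def rec(start):
        if start >= n:
            yield ()
            return
        for rest in rec(start + 1):       # index `start` not in any segment
            yield rest
        for j in range(start, n):         # segment [start, j]
            for rest in rec(j + 1):
                yield ((start, j),) + rest
    return rec(0)


def partition_enumerate(pos, cnt, d, P):
    """Fully explicit enumeration (use only for small n)."""
    pos = np.asarray(pos)
    cnt = np.asarray(cnt, dtype=float)
    best = (0.0, ())
    for segs in all_interval_sets(pos.size):
        sc = sum(segment_score(pos, cnt, i, j, d, P) for i, j in segs)
        if sc > best[0]:
            best = (sc, segs)
    return best[0], list(best[1])


# --- PWM scanning ----------------------------------------------------------

def scan_bruteforce(matrix, seq, threshold):
    """Score every window on both strands one at a time via score_window."""
    from chiptools.pwm_model import score_window, revcomp

    L = matrix.length
    out = []
    for p in range(len(seq) - L + 1):
        w = seq[p:p + L]
        fwd = score_window(matrix, w)
        rev = score_window(matrix, revcomp(w))
        score, strand = (fwd, "+") if fwd >= rev else (rev, "-")
        if score >= threshold:
            out.append((p, strand, score))
    return out


# --- statistics ------------------------------------------------------------

def binom_sf_exact(k_obs, n, p0):
    """P(X >= k_obs) for X ~ Binomial(n, p0) by explicit summation."""
    from math import comb

    return float(sum(comb(n, k) * p0**k * (1 - p0) ** (n - k)
                     for k in range(k_obs, n + 1)))


def welch_oracle(a, b):
    """Textbook Welch t statistic and two-tailed p via the t distribution."""
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)
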