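"""Two-state (signal-rich / signal-poor) genome segmentation.

Each chromosome is partitioned to maximize

    sum of capped tag counts inside rich segments
    - density_threshold * total rich length
    - transition_penalty * number of state switches

with chromosome ends forced to the poor state, so every rich segment pays
the switch penalty at both edges.  A rich segment is worth keeping exactly
where its internal tag density exceeds ``density_threshold``; the penalty
controls segment granularity.  The optimum is found exactly: an optimal
rich segment begins and ends on tag positions, so a linear dynamic program
over sorted tag positions (with a running-max over segment start points)
suffices.

Ties between equal-scoring segmentations are broken toward fewer and
shorter rich segments.  Strand is ignored: histone-modification tags are
not footprint-oriented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeTable, TagCollection


@dataclass
class SegmentationParams:
    """Defaults follow the published histone-track settings: density
    threshold 0.004 tags/bp, transition penalty 20 (applied as -20 per
    state switch), per-position count cutoff 5."""

    density_threshold: float = 0.004
    transition_penalty: float = 20.0
    count_cutoff: int = 5

    def __post_init__(self):
        if self.density_threshold <= 0:
            raise ValueError("density_threshold must be > 0")
        if self.transition_penalty < 0:
            raise ValueError("transition_penalty must be >= 0")
        if self.count_cutoff < 1:
            raise ValueError("count_cutoff must be >= 1")


def _pooled_counts(tags: TagCollection, chrom: str, cutoff: int):
    sub = tags.frame[tags.frame["chrom"] == chrom]
    pooled = sub.groupby("pos", as_index=False)["count"].sum()
    pos = pooled["pos"].to_numpy(dtype=np.int64)
    cnt = np.minimum(pooled["count"].to_numpy(dtype=np.int64), cutoff).astype(float)
    return pos, cnt


def _rich_segments_one_chrom(pos, cnt, d, P):
    """Backtrackable linear DP; returns list of (start_tag_idx, end_tag_idx)."""
    n = pos.size
    if n == 0:
        return []
    pref = np.concatenate([[0.0], np.cumsum(cnt)])
    best = np.zeros(n + 1)          # best[j+1]: optimum over tags 0..j
    choice = np.full(n, -1, dtype=np.int64)   # -1 = skip, else segment start idx
    m_val = -np.inf
    m_idx = -1
    for j in range(n):
        g = best[j] - pref[j] + d * pos[j]
        if g >= m_val:              # >= : later start wins ties (shorter segment)
            m_val = g
            m_idx = j
        cand = pref[j + 1] - d * (pos[j] + 1) + m_val - 2.0 * P
        if cand > best[j]:          # strict: ties prefer no new segment
            best[j + 1] = cand
            choice[j] = m_idx
        else:
            best[j + 1] = best[j]
    segs = []
    j = n - 1
    while j >= 0:
        if choice[j] == -1:
            j -= 1
        else:
            segs.append((int(choice[j]), j))
            j = choice[j] - 1
    segs.reverse()
    return segs


def segmentation_score(segments: pd.DataFrame, tags: TagCollection,
                       params: SegmentationParams) -> float:
    """Objective value of an arbitrary segmentation (for verification)."""
    score = 0.0
    for chrom, seg in segments[segments["state"] == "rich"].groupby("chrom", sort=False):
        pos, cnt = _pooled_counts(tags, chrom, params.count_cutoff)
        pref = np.concatenate([[0.0], np.cumsum(cnt)])
        for s, e in seg[["start", "end"]].itertuples(index=False):
            lo = np.searchsorted(pos, s, side="left")
            hi = np.searchsorted(pos, e, side="left")
            score += (pref[hi] - pref[lo]
                      - params.density_threshold * (e - s)
                      - 2.0 * params.transition_penalty)
    return float(score)


def partition(tags: TagCollection, params: SegmentationParams,
              genome: GenomeTable | None = None) -> pd.DataFrame:
    """Optimal two-state labeling of every chromosome.

    Returns segments tiling each chromosome (columns ``chrom, start, end,
    state``) with adjacent segments of different state; a chromosome with
    no tags is a single poor segment.
    """
    genome = genome or tags.genome
    d, P = params.density_threshold, params.transition_penalty
    rows = []
    for chrom, size in genome.entries:
        pos, cnt = _pooled_counts(tags, chrom, params.count_cutoff)
        segs = _rich_segments_one_chrom(pos, cnt, d, P)
        cur = 0
        for i, j in segs:
            s, e = int(pos[i]), int(pos[j]) + 1
            if s > cur:
                rows.append((chrom, cur, s, "poor"))
            rows.append((chrom, s, e, "rich"))
            cur = e
        if cur < size:
            rows.append((chrom, cur, size, "poor"))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    # coalesce any zero-gap same-state neighbours (can only arise at P=0 ties)
    merged = []
    for row in out.itertuples(index=False):
        if merged and merged[-1][0] == row.chrom and merged[-1][3] == row.state \
                and merged[-1][2] == row.start:
            merged[-1][2] = row.end
        else:
            merged.append([row.chrom, row.start, row.end, row.state])
    return pd.DataFrame(merged, columns=["chrom", "start", "end", "state"])


def boundaries_from_segments(segments: pd.DataFrame, mark: str = "",
                             genome: GenomeTable | None = None) -> pd.DataFrame:
    """Polarity-bearing poor<->rich transition points.

    Each rich segment contributes its left edge with polarity ``+``
    (rich side to the right) and its right edge with polarity ``-``
    (rich side to the left); edges coinciding with chromosome ends are
    excluded.  Returns columns ``chrom, pos, polarity, mark``.
    """
    chrom_ends = {}
    for chrom, seg in segments.groupby("chrom", sort=False):
        chrom_ends[chrom] = (int(seg["start"].min()), int(seg["end"].max()))
    if genome is not None:
        chrom_ends.update({c: (0, l) for c, l in genome.entries})
    rows = []
    rich = segments[segments["state"] == "rich"]
    for row in rich.itertuples(index=False):
        lo, hi = chrom_ends[row.chrom]
        if row.start > lo:
            rows.append((row.chrom, int(row.start), "+", mark))
        if row.end < hi:
            rows.append((row.chrom, int(row.end), "-", mark))
    return pd.DataFrame(rows, columns=["chrom", "pos", "polarity", "mark"])
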