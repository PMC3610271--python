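"""Sliding-window peak calling from shifted, deduplicated ChIP-seq tags.

The procedure: cap the per-position tag multiplicity (default one tag per
unique genomic location), shift + tags downstream and - tags upstream by
``shift`` bp so the two strand pile-ups of a ~150 bp footprint coincide,
pool strands, count tags in every ``window``-bp window, and report window
centers of windows reaching ``tag_threshold`` tags, greedily suppressing
any candidate whose center lies within ``vicinity`` bp of a previously
accepted (higher-count) center so one binding site is counted once.

Candidate windows are anchored at tag positions: an optimal window can
always be shifted right until its left edge sits on a tag without losing
any tag, so the per-bp search space reduces to the tag positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals
from .io_formats import GenomeTable, TagCollection

log = logging.getLogger(__name__)


@dataclass
class PeakCallParams:
    """ChIP-Peak parameters.

    window/shift/vicinity defaults follow the published settings for
    ~260 bp fragments (600/75/600); ``tag_threshold`` is typically chosen
    in 5-10 and defaults to the ENCODE-motif-validated 6.
    """

    window: int = 600
    shift: int = 75
    tag_threshold: int = 6
    vicinity: int = 600
    count_cutoff: int = 1
    repeat_mask: dict | None = None   # chrom -> (starts, ends) half-open

    def __post_init__(self):
        if min(self.window, self.shift, self.vicinity) < 0:
            raise ValueError("window, shift and vicinity must be >= 0")
        if self.tag_threshold < 1:
            raise ValueError("tag_threshold must be >= 1")
        if self.count_cutoff < 1:
            raise ValueError("count_cutoff must be >= 1")


def dedupe_and_shift(tags: TagCollection, params: PeakCallParams) -> TagCollection:
    """Cap per-position multiplicity at ``count_cutoff`` and shift tags
    ``shift`` bp in their 5'->3' direction, clamped to chromosome bounds."""
    capped = tags.deduplicate(params.count_cutoff)
    f = capped.frame.copy()
    delta = np.where(f["strand"] == "+", params.shift, -params.shift)
    f["pos"] = f["pos"] + delta
    sizes = f["chrom"].map(tags.genome.sizes)
    f["pos"] = f["pos"].clip(lower=0, upper=sizes - 1)
    return TagCollection(f, tags.genome)


def call_peaks(tags: TagCollection, params: PeakCallParams) -> pd.DataFrame:
    """Call peaks from deduplicated, shifted tags.

    Returns a frame with columns ``chrom, center, count, start, end``
    sorted by genome order; ``center`` is the window midpoint (rounded
    down) and ``count`` the window tag count.  Peaks whose center falls in
    ``repeat_mask`` are dropped.  Raising the threshold never adds peaks,
    and accepted centers on a chromosome are pairwise >= ``vicinity`` apart.
    """
    W, T, V = params.window, params.tag_threshold, params.vicinity
    rows = []
    for chrom, sub in tags.frame.groupby("chrom", sort=False):
        # pool strands into per-position counts
        pooled = sub.groupby("pos", as_index=False)["count"].sum()
        pos = pooled["pos"].to_numpy()
        cnt = pooled["count"].to_numpy()
        if pos.size == 0:
            continue
        pref = np.concatenate([[0], np.cumsum(cnt)])
        hi = np.searchsorted(pos, pos + W, side="left")
        counts = pref[hi] - pref[np.arange(pos.size)]
        cand = counts >= T
        cpos, ccnt = pos[cand], counts[cand]
        if cpos.size == 0:
            continue
        order = np.lexsort((cpos, -ccnt))   # descending count, then leftmost
        accepted = []
        for i in order:
            center = int(cpos[i]) + W // 2
            if all(abs(center - a) >= V for a in accepted):
                accepted.append(center)
                rows.append((chrom, center, int(ccnt[i]), int(cpos[i]),
                             int(cpos[i]) + W))
    peaks = pd.DataFrame(rows, columns=["chrom", "center", "count", "start", "end"])
    if params.repeat_mask:
        keep = np.ones(len(peaks), dtype=bool)
        for chrom, (ms, me) in params.repeat_mask.items():
            sel = peaks["chrom"] == chrom
            if sel.any():
                inside = intervals.contains(ms, me, peaks.loc[sel, "center"].to_numpy())
                keep[np.nonzero(sel.to_numpy())[0][inside]] = False
        dropped = int((~keep).sum())
        if dropped:
            log.info("call_peaks: %d peaks dropped in repeat regions", dropped)
        peaks = peaks[keep].reset_index(drop=True)
    order = {name: i for i, name in enumerate(tags.genome.names)}
    peaks = peaks.sort_values(["chrom", "center"],
                              key=lambda col: col.map(order) if col.name == "chrom" else col,
                              kind="stable").reset_index(drop=True)
    return peaks


def run_peak_calling(tags: TagCollection, params: PeakCallParams) -> pd.DataFrame:
    """Convenience: dedupe_and_shift then call_peaks."""
    return call_peaks(dedupe_and_shift(tags, params), params)


@dataclass(frozen=True)
class MappingSummary:
    total_reads: int
    unique_mapped: int
    unique_positions: int | None
    mapped_pct: float           # to one decimal, as conventionally reported

    def __str__(self) -> str:
        s = (f"{self.unique_mapped:,} of {self.total_reads:,} reads "
             f"({self.mapped_pct}%) mapped to unique positions")
        if self.unique_positions is not None:
            s += f"; {self.unique_positions:,} distinct genome positions hit"
        return s


def mapping_summary(total_reads: int, unique_mapped: int,
                    unique_positions: int | None = None) -> MappingSummary:
    """Read-mapping bookkeeping with the percentage to one decimal."""
    if unique_mapped > total_reads:
        raise ValueError("unique_mapped exceeds total_reads")
    pct = round(100.0 * unique_mapped / total_reads, 1)
    return MappingSummary(total_reads, unique_mapped, unique_positions, pct)
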