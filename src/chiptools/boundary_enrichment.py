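"""Co-localization statistics between sites and chromatin-domain boundaries.

Boundary tables carry ``chrom, pos, polarity`` with polarity ``+`` meaning
the modification-rich side lies to the right and ``-`` to the left.
Signed distances are measured positive toward the rich side, so "matched
on the rich side" is simply a non-negative signed distance.  Enrichment
against per-chromosome random controls uses a one-sided exact binomial
test with the null proportion estimated from the control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeTable


def _site_positions(sites, chrom: str) -> np.ndarray:
    f = sites
    col = "center" if "center" in f.columns else "pos"
    return np.sort(f.loc[f["chrom"] == chrom, col].to_numpy())


def match_sites_to_boundaries(boundaries: pd.DataFrame, sites: pd.DataFrame,
                              radius: int = 2500) -> pd.DataFrame:
    """Nearest site within ``radius`` (closed) of each boundary.

    Returns one row per boundary with ``matched``, the signed ``distance``
    (positive toward the rich side) and ``side`` ('rich'/'poor'; a site at
    distance exactly 0 counts as rich).
    """
    out = boundaries.copy().reset_index(drop=True)
    matched = np.zeros(len(out), dtype=bool)
    distance = np.full(len(out), np.nan)
    side = np.full(len(out), "", dtype=object)
    for chrom, bsub in out.groupby("chrom", sort=False):
        spos = _site_positions(sites, chrom)
        if spos.size == 0:
            continue
        bpos = bsub["pos"].to_numpy()
        j = np.searchsorted(spos, bpos)
        left = np.clip(j - 1, 0, spos.size - 1)
        right = np.clip(j, 0, spos.size - 1)
        d_left = bpos - spos[left]
        d_right = spos[right] - bpos
        use_right = (j == 0) | ((j < spos.size) & (d_right <= d_left))
        raw = np.where(use_right, spos[right] - bpos, spos[left] - bpos)
        ok = np.abs(raw) <= radius
        signed = np.where(bsub["polarity"].to_numpy() == "+", raw, -raw)
        idx = bsub.index.to_numpy()
        matched[idx] = ok
        distance[idx] = np.where(ok, signed, np.nan)
        side[idx] = np.where(ok, np.where(signed >= 0, "rich", "poor"), "")
    out["matched"] = matched
    out["distance"] = distance
    out["side"] = side
    return out


def colocalize_boundaries(a: pd.DataFrame, b: pd.DataFrame, radius: int = 2500,
                          require_opposite_polarity: bool = True):
    """One-to-one greedy pairing of a-boundaries with the nearest
    b-boundary within ``radius`` (optionally of opposite polarity).

    Returns (pairs, unmatched_a): ``pairs`` has columns ``a_index, b_index,
    distance``; ``unmatched_a`` is the index of a-rows left unpaired.
    """
    a = a.reset_index(drop=True)
    b = b.reset_index(drop=True)
    cand = []
    for chrom, asub in a.groupby("chrom", sort=False):
        bsub = b[b["chrom"] == chrom]
        if bsub.empty:
            continue
        bpos = bsub["pos"].to_numpy()
        order = np.argsort(bpos, kind="stable")
        bpos_sorted = bpos[order]
        bidx_sorted = bsub.index.to_numpy()[order]
        bpol_sorted = bsub["polarity"].to_numpy()[order]
        for ai, apos, apol in zip(asub.index, asub["pos"], asub["polarity"]):
            lo = np.searchsorted(bpos_sorted, apos - radius, side="left")
            hi = np.searchsorted(bpos_sorted, apos + radius, side="right")
            for k in range(lo, hi):
                if require_opposite_polarity and bpol_sorted[k] == apol:
                    continue
                cand.append((abs(int(bpos_sorted[k]) - int(apos)),
                             int(ai), int(bidx_sorted[k])))
    cand.sort()
    used_a, used_b, rows = set(), set(), []
    for dist, ai, bi in cand:
        if ai in used_a or bi in used_b:
            continue
        used_a.add(ai)
        used_b.add(bi)
        rows.append((ai, bi, dist))
    pairs = pd.DataFrame(rows, columns=["a_index", "b_index", "distance"])
    unmatched = a.index.difference(pairs["a_index"] if len(pairs) else [])
    return pairs, unmatched


def classify_vs_genes(boundaries: pd.DataFrame, genes, radius: int = 2500) -> pd.Series:
    """Exhaustive disjoint partition of boundaries into 'tss' / 'tes' /
    'neither' by proximity within ``radius``; TSS takes precedence."""
    bnd = boundaries.reset_index(drop=True)
    tss, tes = {}, {}
    for g in genes:
        tss.setdefault(g.chrom, []).append(g.tss)
        tes.setdefault(g.chrom, []).append(g.tes)
    labels = np.full(len(bnd), "neither", dtype=object)
    for chrom, bsub in bnd.groupby("chrom", sort=False):
        bpos = bsub["pos"].to_numpy()
        for positions, label in ((tss.get(chrom), "tss"), (tes.get(chrom), "tes")):
            if not positions:
                continue
            arr = np.sort(np.asarray(positions))
            j = np.clip(np.searchsorted(arr, bpos), 0, arr.size - 1)
            near = np.minimum(np.abs(arr[j] - bpos),
                              np.abs(arr[np.clip(j - 1, 0, arr.size - 1)] - bpos))
            hit = near <= radius
            idx = bsub.index.to_numpy()[hit]
            for i in idx:
                if labels[i] == "neither":
                    labels[i] = label
    return pd.Series(labels, index=bnd.index, name="class")


def sample_random_sites(template: pd.DataFrame, genome: GenomeTable,
                        seed) -> pd.DataFrame:
    """Uniform random positions, the same number per chromosome as the
    template sites; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    rows = []
    counts = template.groupby("chrom", sort=False).size()
    for chrom in genome.names:
        k = int(counts.get(chrom, 0))
        if k == 0:
            continue
        pos = rng.integers(0, genome.sizes[chrom], size=k)
        rows.append(pd.DataFrame({"chrom": chrom, "pos": np.sort(pos)}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos"])
    return pd.concat(rows, ignore_index=True)


def truncate_pct(k: int, n: int, decimals: int = 2) -> float:
    """Percentage truncated (not rounded) toward zero, the convention used
    in tabulated boundary co-localization reports."""
    scale = 10 ** decimals
    return math.floor(100.0 * k / n * scale + 1e-9) / scale


def round_pct(k: int, n: int, decimals: int = 1) -> float:
    """Percentage rounded to ``decimals``, the convention for in-text
    match fractions."""
    return round(100.0 * k / n, decimals)


@dataclass(frozen=True)
class EnrichmentResult:
    n: int
    k_obs: int
    k_rand: int
    control_trials: int
    proportion_obs: float
    proportion_rand: float
    pct_obs: float                # truncated to two decimals
    pct_rand: float
    p0: float
    p_value: float
    p0_floored: bool


def enrichment_test(n: int, k_obs: int, k_rand: int,
                    control_trials: int = 1) -> EnrichmentResult:
    """One-sided exact binomial enrichment of observed matches over the
    random control.

    The null match probability is ``k_rand / (n * control_trials)`` (the
    control may pool several random replicates for a steadier estimate);
    p = P(Binomial(n, p0) >= k_obs).  A control with zero matches gets the
    continuity floor p0 = 0.5/n and is flagged.
    """
    if not (0 <= k_obs <= n):
        raise ValueError("k_obs out of range")
    if not (0 <= k_rand <= n * control_trials):
        raise ValueError("k_rand out of range")
    floored = k_rand == 0
    p0 = 0.5 / n if floored else k_rand / (n * control_trials)
    p_value = float(stats.binom.sf(k_obs - 1, n, p0))
    return EnrichmentResult(
        n=n, k_obs=k_obs, k_rand=k_rand, control_trials=control_trials,
        proportion_obs=k_obs / n,
        proportion_rand=k_rand / (n * control_trials),
        pct_obs=truncate_pct(k_obs, n),
        pct_rand=truncate_pct(k_rand, n * control_trials),
        p0=p0, p_value=p_value, p0_floored=floored,
    )


def nearest_distance_distribution(boundaries: pd.DataFrame, sites: pd.DataFrame,
                                  side: str = "rich", k: int = 2000) -> np.ndarray:
    """The k smallest boundary-to-nearest-site distances on one side.

    For each boundary, the distance to the nearest site strictly on the
    requested side (rich = toward the polarity arrow, a site at the
    boundary itself counting as rich); boundaries with no site on that
    side are skipped.  Returns the k smallest distances, sorted.
    """
    if side not in ("rich", "poor"):
        raise ValueError("side must be 'rich' or 'poor'")
    dists = []
    for chrom, bsub in boundaries.groupby("chrom", sort=False):
        spos = _site_positions(sites, chrom)
        if spos.size == 0:
            continue
        for bpos, pol in zip(bsub["pos"].to_numpy(), bsub["polarity"].to_numpy()):
            rightward = (pol == "+") == (side == "rich")
            # a site exactly at the boundary belongs to the rich side
            if rightward:
                j = np.searchsorted(spos, bpos, side="left" if side == "rich" else "right")
                if j < spos.size:
                    dists.append(int(spos[j] - bpos))
            else:
                j = np.searchsorted(spos, bpos, side="right" if side == "rich" else "left") - 1
                if j >= 0:
                    dists.append(int(bpos - spos[j]))
    dists = np.sort(np.asarray(dists, dtype=np.int64))
    if k > dists.size:
        warnings.warn(f"only {dists.size} distances available (< k={k})")
        return dists
    return dists[:k]


def lamina_alignment(lads, sites: pd.DataFrame, params, genome: GenomeTable,
                     radius: int = 2500):
    """Site profile around LAD edges oriented lamina -> nuclear interior.

    ``lads`` is a list of (chrom, start, end) intervals.  Positive profile
    distances point into the lamin-poor interior.  Returns (profile,
    summary) where summary counts boundaries with a site within ``radius``
    and splits matches by side.
    """
    from .positional_correlation import CorrelationParams, correlate

    lads = list(lads)
    if not lads:
        raise ValueError("lamina_alignment: empty LAD list")
    rows = []
    for chrom, start, end in lads:
        size = genome.sizes[chrom]
        if start > 0:
            # interior lies to the left: '-' reference flips the sign
            rows.append((chrom, int(start), "-", 1))
        if end < size:
            rows.append((chrom, int(end), "+", 1))
    ref = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
    oriented = CorrelationParams(params.bin_size, params.span, params.cap,
                                 oriented=True)
    profile = correlate(ref, sites, oriented, genome)

    boundaries = ref.rename(columns={"strand": "polarity"})[["chrom", "pos", "polarity"]]
    # polarity as stored points toward the interior after the flip above:
    # '+' edge has interior to the right.  Reuse the matcher with "rich" =
    # interior (lamin-poor) side.
    matches = match_sites_to_boundaries(boundaries, sites, radius=radius)
    summary = {
        "n_boundaries": len(boundaries),
        "n_matched": int(matches["matched"].sum()),
        "matched_lamin_poor": int((matches["side"] == "rich").sum()),
        "matched_lamin_rich": int((matches["side"] == "poor").sum()),
        "pct_matched": round_pct(int(matches["matched"].sum()), len(boundaries)),
    }
    return profile, summary
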