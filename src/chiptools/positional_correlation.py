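"""Binned, globally normalized positional correlation between feature sets.

``correlate`` computes, for every reference feature, the (multiplicity-
capped) number of target features at each signed distance, bins the
distances, and normalizes each bin by the genome-wide average target
density, so a profile value of 1 means "no enrichment over the genome
average".  Distances are ``target - reference``; for orientation-aware
profiles the sign is flipped for minus-strand references.  A distance of
exactly 0 falls in the first positive bin.

Specializations: strand cross-correlation (fragment-length footprint
estimation from + vs - tag spacing), the ENCODE-style motif-enrichment
validation of peak lists, tag attribution to predicted sites with the
score-class log-linear fit, and oriented TSS profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals
from .io_formats import GenomeTable, TagCollection


@dataclass
class CorrelationParams:
    bin_size: int = 50
    span: int = 2500              # bp considered on each side
    cap: int = 10                 # co-localized count cap per position
    oriented: bool = False

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if self.span < self.bin_size:
            raise ValueError("span must be >= bin_size")


@dataclass
class CorrelationProfile:
    bin_centers: np.ndarray       # signed bp
    values: np.ndarray            # fold over genome-wide average
    raw: np.ndarray               # capped co-localized counts per bin
    n_reference: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers,
                             "raw": self.raw, "normalized": self.values})

    def to_tsv(self, path) -> None:
        self.as_frame().to_csv(path, sep="\t", index=False)


def feature_frame(obj) -> pd.DataFrame:
    """Normalize a feature set to columns chrom, pos[, strand], count.

    Accepts a TagCollection, or any DataFrame with a ``pos`` or ``center``
    column (``center`` preferred: peak and site tables carry both a window
    start and a center).
    """
    if isinstance(obj, TagCollection):
        return obj.frame
    f = obj.copy()
    if "pos" not in f.columns or "center" in f.columns:
        f["pos"] = f["center"]
    if "count" not in f.columns:
        f["count"] = 1
    return f


def _masked(frame: pd.DataFrame, mask: dict) -> pd.DataFrame:
    keep = np.ones(len(frame), dtype=bool)
    pos = frame["pos"].to_numpy()
    for chrom, (ms, me) in mask.items():
        sel = (frame["chrom"] == chrom).to_numpy()
        if sel.any():
            inside = intervals.contains(ms, me, pos[sel])
            keep[np.nonzero(sel)[0][inside]] = False
    return frame[keep]


def correlate(reference, target, params: CorrelationParams, genome: GenomeTable,
              repeat_mask: dict | None = None) -> CorrelationProfile:
    """Normalized frequency of targets as a function of signed distance to
    references.

    value = (bin count / n_reference / bin_size) / (total target count /
    genome length); uniform targets therefore give a flat profile of 1.
    ``repeat_mask`` removes targets inside the given intervals before
    correlation.
    """
    ref = feature_frame(reference)
    tgt = feature_frame(target)
    if repeat_mask:
        tgt = _masked(tgt, repeat_mask)
    b, span, cap = params.bin_size, params.span, params.cap
    n_half = -(-span // b)                     # ceil: span rounded up to bins
    n_bins = 2 * n_half
    centers = (np.arange(n_bins) - n_half + 0.5) * b

    ref_w = ref["count"].clip(upper=cap).to_numpy(dtype=float)
    tgt_w = tgt["count"].clip(upper=cap).to_numpy(dtype=float)
    n_reference = float(ref_w.sum())
    if n_reference == 0:
        raise ValueError("correlate: no reference features")
    total_target = float(tgt_w.sum())

    raw = np.zeros(n_bins)
    for chrom, rsub in ref.groupby("chrom", sort=False):
        tsel = (tgt["chrom"] == chrom).to_numpy()
        if not tsel.any():
            continue
        tpos = tgt["pos"].to_numpy()[tsel]
        tw = tgt_w[tsel]
        order = np.argsort(tpos, kind="stable")
        tpos, tw = tpos[order], tw[order]
        rpos = rsub["pos"].to_numpy()
        rw = rsub["count"].clip(upper=cap).to_numpy(dtype=float)
        lo = np.searchsorted(tpos, rpos - n_half * b, side="left")
        hi = np.searchsorted(tpos, rpos + n_half * b, side="left")
        lens = hi - lo
        total = int(lens.sum())
        if total == 0:
            continue
        flat = (np.arange(total)
                - np.repeat(np.cumsum(lens) - lens, lens)
                + np.repeat(lo, lens))
        d = tpos[flat] - np.repeat(rpos, lens)
        if params.oriented and "strand" in rsub.columns:
            flip = np.repeat((rsub["strand"] == "-").to_numpy(), lens)
            d = np.where(flip, -d, d)
        w = tw[flat] * np.repeat(rw, lens)
        idx = np.floor_divide(d, b) + n_half
        ok = (idx >= 0) & (idx < n_bins)
        np.add.at(raw, idx[ok], w[ok])

    density = total_target / genome.total_length
    if density == 0:
        values = np.zeros(n_bins)
    else:
        values = (raw / n_reference / b) / density
    return CorrelationProfile(centers, values, raw, int(round(n_reference)))


# ---------------------------------------------------------------------------
# strand cross-correlation
# ---------------------------------------------------------------------------

def strand_cross_correlation(tags: TagCollection, params: CorrelationParams,
                             repeat_mask: dict | None = None):
    """Profile of minus tags around plus tags; the modal positive distance
    estimates the protected-fragment (footprint) length.

    Returns (profile, modal_distance) with modal_distance the bin center of
    the maximum over positive distances.
    """
    plus = tags.subset_strand("+")
    minus = tags.subset_strand("-")
    if len(plus) == 0 or len(minus) == 0:
        raise ValueError("strand_cross_correlation: one strand is empty")
    profile = correlate(plus, minus, params, tags.genome, repeat_mask=repeat_mask)
    pos_side = profile.bin_centers > 0
    modal = float(profile.bin_centers[pos_side][np.argmax(profile.values[pos_side])])
    return profile, modal


# ---------------------------------------------------------------------------
# motif enrichment validation (ENCODE criteria)
# ---------------------------------------------------------------------------

@dataclass
class MotifEnrichment:
    bin_centers: np.ndarray
    frequency: np.ndarray         # fraction of peaks with >=1 site per bin
    central_frequency: float      # fraction with a site within +/- window/2
    enrichment_factor: float      # central / mean flank frequency
    encode_pass: bool
    n_peaks: int


def motif_enrichment_profile(peaks: pd.DataFrame, sites: pd.DataFrame,
                             window: int = 300, span: int = 10000,
                             flank: tuple = (3000, 10000)) -> MotifEnrichment:
    """Fraction of peaks with a predicted site at each center-to-center
    distance, the central occurrence frequency, and the fold enrichment of
    the central window over the distal flanks.

    The ENCODE guideline is passed when the motif is >= 4-fold enriched and
    occurs in >= 10% of the peak regions.
    """
    if span < window:
        raise ValueError("span must be >= window")
    if len(peaks) == 0 or len(sites) == 0:
        raise ValueError("motif_enrichment_profile: empty input")
    pk = feature_frame(peaks)
    st = feature_frame(sites)
    n_half = -(-span // window)
    n_bins = 2 * n_half
    centers = (np.arange(n_bins) - n_half + 0.5) * window
    hit = np.zeros((len(pk), n_bins), dtype=bool)
    central = np.zeros(len(pk), dtype=bool)
    row = 0
    for chrom, psub in pk.groupby("chrom", sort=False):
        spos = np.sort(st.loc[st["chrom"] == chrom, "pos"].to_numpy())
        for p in psub["pos"].to_numpy():
            lo = np.searchsorted(spos, p - n_half * window, side="left")
            hi = np.searchsorted(spos, p + n_half * window, side="left")
            d = spos[lo:hi] - p
            idx = np.floor_divide(d, window) + n_half
            hit[row, idx[(idx >= 0) & (idx < n_bins)]] = True
            central[row] = bool(((d >= -window // 2) & (d <= window // 2)).any())
            row += 1
    freq = hit[:row].mean(axis=0)
    central_frequency = float(central[:row].mean())
    in_flank = (np.abs(centers) >= flank[0]) & (np.abs(centers) <= flank[1])
    flank_frequency = float(freq[in_flank].mean())
    factor = central_frequency / flank_frequency if flank_frequency > 0 else np.inf
    return MotifEnrichment(centers, freq, central_frequency, factor,
                           bool(factor >= 4.0 and central_frequency >= 0.10),
                           n_peaks=row)


# ---------------------------------------------------------------------------
# tag attribution to predicted sites and the score-occupancy fit
# ---------------------------------------------------------------------------

def attribute_tags_to_sites(tags: TagCollection, sites: pd.DataFrame,
                            max_dist: int = 200) -> pd.DataFrame:
    """Attribute + tags to the closest downstream site and - tags to the
    closest upstream site, both within ``max_dist`` bp (strict); unassigned
    tags are dropped and each tag is assigned at most once.

    Returns a copy of ``sites`` with an ``attributed_tags`` column.
    """
    st = sites.copy()
    st["attributed_tags"] = 0
    for chrom, ssub in st.groupby("chrom", sort=False):
        centers = ssub["center"].to_numpy()
        order = np.argsort(centers, kind="stable")
        centers_sorted = centers[order]
        idx_sorted = ssub.index.to_numpy()[order]
        counts = np.zeros(centers_sorted.size, dtype=np.int64)
        tsub = tags.frame[tags.frame["chrom"] == chrom]
        for strand, sign in (("+", 1), ("-", -1)):
            tt = tsub[tsub["strand"] == strand]
            if tt.empty:
                continue
            pos = tt["pos"].to_numpy()
            w = tt["count"].to_numpy()
            if sign > 0:   # nearest site center >= tag position
                j = np.searchsorted(centers_sorted, pos, side="left")
                ok = (j < centers_sorted.size)
                dist = np.where(ok, centers_sorted[np.minimum(j, centers_sorted.size - 1)] - pos,
                                max_dist)
            else:          # nearest site center <= tag position
                j = np.searchsorted(centers_sorted, pos, side="right") - 1
                ok = j >= 0
                dist = np.where(ok, pos - centers_sorted[np.maximum(j, 0)], max_dist)
            ok &= dist < max_dist
            np.add.at(counts, j[ok], w[ok])
        st.loc[idx_sorted, "attributed_tags"] = counts
    return st


@dataclass
class CoverageFit:
    table: pd.DataFrame           # score_class (midpoint), n_sites, mean_tags
    slope: float                  # d log(mean) / d score, natural log
    intercept: float
    r: float


def coverage_by_score_class(sites: pd.DataFrame, class_width: float = 1.0) -> CoverageFit:
    """Mean attributed tag count per matrix-score class, with a weighted
    log-linear fit of mean count against class midpoint.

    The fitted slope is on the natural-log scale, i.e. mean ~ exp(slope *
    score); classes with no sites or zero mean are omitted.
    """
    import statsmodels.api as sm

    cls = np.floor(sites["score"].to_numpy() / class_width)
    grp = pd.DataFrame({
        "mid": (cls + 0.5) * class_width,
        "tags": sites["attributed_tags"].to_numpy(),
    }).groupby("mid")
    table = grp.agg(n_sites=("tags", "size"), mean_tags=("tags", "mean")).reset_index()
    usable = table[table["mean_tags"] > 0]
    if len(usable) < len(table):
        warnings.warn(f"{len(table) - len(usable)} score classes with zero mean omitted")
    if len(usable) < 2:
        raise ValueError("need >= 2 usable score classes for the log-linear fit")
    x = usable["mid"].to_numpy()
    y = np.log(usable["mean_tags"].to_numpy())
    w = usable["n_sites"].to_numpy(dtype=float)
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    slope = float(fit.params[1])
    # weighted Pearson correlation (0 for a degenerate fit)
    wm = w / w.sum()
    xc, yc = x - (wm * x).sum(), y - (wm * y).sum()
    denom = np.sqrt((wm * xc**2).sum() * (wm * yc**2).sum())
    r = float((wm * xc * yc).sum() / denom) if denom > 0 else 0.0
    return CoverageFit(table=table, slope=slope, intercept=float(fit.params[0]), r=r)


# ---------------------------------------------------------------------------
# oriented TSS profiles
# ---------------------------------------------------------------------------

def tss_profile(features, genes, params: CorrelationParams,
                genome: GenomeTable) -> CorrelationProfile:
    """Orientation-aware correlation of features around gene TSSs; positive
    distances point downstream (into the gene)."""
    if not genes:
        raise ValueError("tss_profile: empty gene set")
    ref = pd.DataFrame({
        "chrom": [g.chrom for g in genes],
        "pos": [g.tss for g in genes],
        "strand": [g.strand for g in genes],
        "count": 1,
    })
    oriented = CorrelationParams(params.bin_size, params.span, params.cap, oriented=True)
    return correlate(ref, features, oriented, genome)
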