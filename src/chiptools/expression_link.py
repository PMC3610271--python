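"""Integration of binding sites/peaks with gene annotation and two-condition
expression.

Covers: genomic-compartment assignment and densities, regulation classes
from wild-type minus knock-out expression differences, 11-bin expression
grouping for TSS metaprofiles, bound-vs-unbound expression comparison
(Welch t), and site densities per gene class.

Expression differences are wt - ko on the array's log scale: a gene
up-regulated by the factor is higher in wild type.  Class thresholds are
strict inequalities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals
from .io_formats import GenomeTable

log = logging.getLogger(__name__)

COMPARTMENT_PRECEDENCE = ["utr5", "utr3", "coding_exon", "intron",
                          "upstream5kb", "downstream5kb", "intergenic"]


def _gene_flanks(g, flank: int):
    """(upstream, downstream) half-open intervals of a gene, strand-aware."""
    lo, hi = g.body
    if g.strand == "+":
        return (max(0, lo - flank), lo), (hi, hi + flank)
    return (hi, hi + flank), (max(0, lo - flank), lo)


def annotate_compartments(features: pd.DataFrame, genes, genome: GenomeTable,
                          flank: int = 5000):
    """Assign each feature to exactly one genomic compartment and report
    per-compartment counts, spans and densities.

    Precedence: 5'UTR > 3'UTR > coding exon > intron > 5 kb upstream >
    5 kb downstream > intergenic; the compartments therefore partition the
    genome and each feature is counted once.  UTR/exon compartments are
    skipped when the annotation carries no substructure (the whole gene
    body then counts as intron).  Returns (table, assignment).
    """
    raw = {name: {} for name in COMPARTMENT_PRECEDENCE[:-1]}

    def add(comp, chrom, s, e):
        raw[comp].setdefault(chrom, ([], []))
        raw[comp][chrom][0].append(s)
        raw[comp][chrom][1].append(e)

    for g in genes:
        for comp, ivs in (("utr5", g.utr5), ("utr3", g.utr3), ("coding_exon", g.exons)):
            for s, e in ivs:
                add(comp, g.chrom, s, e)
        add("intron", g.chrom, *g.body)
        up, down = _gene_flanks(g, flank)
        add("upstream5kb", g.chrom, *up)
        add("downstream5kb", g.chrom, *down)

    # carve the precedence partition chromosome by chromosome
    part = {name: {} for name in COMPARTMENT_PRECEDENCE[:-1]}
    spans = dict.fromkeys(COMPARTMENT_PRECEDENCE, 0)
    for chrom, size in genome.entries:
        taken = (np.array([], dtype=np.int64), np.array([], dtype=np.int64))
        for comp in COMPARTMENT_PRECEDENCE[:-1]:
            if chrom in raw[comp]:
                s, e = raw[comp][chrom]
                s = np.clip(np.asarray(s, dtype=np.int64), 0, size)
                e = np.clip(np.asarray(e, dtype=np.int64), 0, size)
                keep = s < e
                s, e = intervals.subtract(s[keep], e[keep], *taken)
            else:
                s = e = np.array([], dtype=np.int64)
            part[comp][chrom] = (s, e)
            spans[comp] += intervals.total_length(s, e)
            taken = intervals.merge(np.concatenate([taken[0], s]),
                                    np.concatenate([taken[1], e]))
        spans["intergenic"] += size - intervals.total_length(*taken)

    col = "center" if "center" in features.columns else "pos"
    assignment = np.full(len(features), "intergenic", dtype=object)
    feats = features.reset_index(drop=True)
    for chrom, fsub in feats.groupby("chrom", sort=False):
        pos = fsub[col].to_numpy()
        idx = fsub.index.to_numpy()
        unassigned = np.ones(pos.size, dtype=bool)
        for comp in COMPARTMENT_PRECEDENCE[:-1]:
            s, e = part[comp].get(chrom, (np.array([]), np.array([])))
            if len(s) == 0 or not unassigned.any():
                continue
            inside = intervals.contains(s, e, pos) & unassigned
            assignment[idx[inside]] = comp
            unassigned &= ~inside
    assignment = pd.Series(assignment, index=feats.index, name="compartment")

    rows = []
    for comp in COMPARTMENT_PRECEDENCE:
        n = int((assignment == comp).sum())
        mb = spans[comp] / 1e6
        rows.append((comp, n, mb, n / mb if mb > 0 else np.nan))
    table = pd.DataFrame(rows, columns=["compartment", "count", "span_mb", "per_mb"])
    return table, assignment


@dataclass
class RegulationClasses:
    up: set
    down: set
    non: set
    controls: dict                 # class name -> size-matched random gene set
    excluded: list                 # ids present in only one condition
    delta: pd.Series               # wt - ko for all common genes

    @property
    def sizes(self) -> dict:
        return {"up": len(self.up), "down": len(self.down), "non": len(self.non)}


def classify_regulation(expr_wt: pd.Series, expr_ko: pd.Series,
                        up_threshold: float = 0.5, down_threshold: float = -0.5,
                        non_band: float = 0.05, seed=0) -> RegulationClasses:
    """Regulation classes from the wt - ko expression difference.

    up: delta > up_threshold; down: delta < down_threshold;
    non: |delta| < non_band (all strict).  Genes present in only one table
    are excluded and logged.  Size-matched random control gene sets are
    drawn per class from the common genes with the given seed.
    """
    common = expr_wt.index.intersection(expr_ko.index)
    excluded = sorted(set(expr_wt.index).symmetric_difference(expr_ko.index))
    if excluded:
        log.info("classify_regulation: %d genes present in one condition only",
                 len(excluded))
    delta = (expr_wt[common] - expr_ko[common]).astype(float)
    up = set(delta.index[delta > up_threshold])
    down = set(delta.index[delta < down_threshold])
    non = set(delta.index[delta.abs() < non_band])
    rng = np.random.default_rng(seed)
    pool = np.asarray(common)
    controls = {
        name: set(rng.choice(pool, size=min(len(members), pool.size), replace=False))
        for name, members in (("up", up), ("down", down), ("non", non))
    }
    return RegulationClasses(up=up, down=down, non=non, controls=controls,
                             excluded=excluded, delta=delta)


EXPRESSION_BIN_LABELS = ["<3"] + [f"{lo}-{lo+1}" for lo in range(3, 12)] + [">12"]


def expression_bins(expr: pd.Series, low: int = 3, high: int = 12) -> dict:
    """Split genes into the 11 conventional expression groups
    (<3, 3-4, ..., 11-12, >12); interior bins are half-open [lo, hi)."""
    groups = {label: [] for label in EXPRESSION_BIN_LABELS}
    for gid, v in expr.items():
        if v < low:
            groups["<3"].append(gid)
        elif v >= high:
            groups[">12"].append(gid)
        else:
            lo = int(np.floor(v))
            groups[f"{lo}-{lo+1}"].append(gid)
    return groups


@dataclass(frozen=True)
class BoundVsUnbound:
    n_bound: int
    n_unbound: int
    mean_bound: float
    mean_unbound: float
    t: float
    p: float


def genes_bound_by_peaks(genes, peaks: pd.DataFrame, upstream: int = 5000) -> set:
    """Genes with >= 1 peak center in the ``upstream`` bp window 5' of the
    TSS (strand-aware, closed at both ends)."""
    bound = set()
    by_chrom = {}
    for chrom, sub in peaks.groupby("chrom", sort=False):
        by_chrom[chrom] = np.sort(sub["center"].to_numpy())
    for g in genes:
        centers = by_chrom.get(g.chrom)
        if centers is None:
            continue
        if g.strand == "+":
            lo, hi = g.tss - upstream, g.tss
        else:
            lo, hi = g.tss, g.tss + upstream
        if np.searchsorted(centers, hi, side="right") > np.searchsorted(centers, lo, side="left"):
            bound.add(g.id)
    return bound


def bound_vs_unbound_expression(genes, peaks: pd.DataFrame, expr: pd.Series,
                                upstream: int = 5000) -> BoundVsUnbound:
    """Mean expression of promoter-bound vs unbound genes with a two-tailed
    Welch (unequal-variance) t-test."""
    bound_ids = genes_bound_by_peaks(genes, peaks, upstream)
    ids = [g.id for g in genes if g.id in expr.index]
    a = expr[[i for i in ids if i in bound_ids]].to_numpy(dtype=float)
    b = expr[[i for i in ids if i not in bound_ids]].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("bound_vs_unbound_expression: a group is empty")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return BoundVsUnbound(a.size, b.size, float(a.mean()), float(b.mean()),
                          float(t), float(p))


def site_density_by_gene_class(sites: pd.DataFrame, peaks: pd.DataFrame,
                               classes: RegulationClasses, genes,
                               genome: GenomeTable, flank: int = 5000) -> pd.DataFrame:
    """Predicted-site and occupied-site densities (per Mb) over the gene
    body +/- flank span of each regulation class, plus intergenic.

    Empty classes are omitted with a warning; densities are independent of
    gene order.
    """
    genes_by_id = {g.id: g for g in genes}
    scol = "center" if "center" in sites.columns else "pos"
    pcol = "center" if "center" in peaks.columns else "pos"

    def span_density(ivs_by_chrom):
        span = 0
        n_sites = 0
        n_peaks = 0
        for chrom, (s, e) in ivs_by_chrom.items():
            size = genome.sizes[chrom]
            s = np.clip(np.asarray(s, dtype=np.int64), 0, size)
            e = np.clip(np.asarray(e, dtype=np.int64), 0, size)
            ms, me = intervals.merge(s, e)
            span += intervals.total_length(ms, me)
            sp = sites.loc[sites["chrom"] == chrom, scol].to_numpy()
            pp = peaks.loc[peaks["chrom"] == chrom, pcol].to_numpy()
            n_sites += int(intervals.contains(ms, me, sp).sum())
            n_peaks += int(intervals.contains(ms, me, pp).sum())
        return span, n_sites, n_peaks

    def class_intervals(ids):
        ivs = {}
        for gid in ids:
            g = genes_by_id.get(gid)
            if g is None:
                continue
            lo, hi = g.body
            ivs.setdefault(g.chrom, ([], []))
            ivs[g.chrom][0].append(max(0, lo - flank))
            ivs[g.chrom][1].append(hi + flank)
        return ivs

    rows = []
    for name, ids in (("up", classes.up), ("down", classes.down), ("non", classes.non)):
        if not ids:
            warnings.warn(f"gene class {name!r} is empty; omitted")
            continue
        span, ns, npk = span_density(class_intervals(ids))
        mb = span / 1e6
        rows.append((name, len(ids), mb,
                     ns / mb if mb else np.nan, npk / mb if mb else np.nan))

    all_ivs = class_intervals(genes_by_id.keys())
    genic = {c: intervals.merge(np.asarray(s), np.asarray(e))
             for c, (s, e) in all_ivs.items()}
    inter = {}
    for chrom, size in genome.entries:
        gs, ge = genic.get(chrom, (np.array([], dtype=np.int64),) * 2)
        inter[chrom] = intervals.subtract([0], [size], gs, ge)
    span, ns, npk = span_density(inter)
    mb = span / 1e6
    rows.append(("intergenic", 0, mb,
                 ns / mb if mb else np.nan, npk / mb if mb else np.nan))
    return pd.DataFrame(rows, columns=["class", "n_genes", "span_mb",
                                       "predicted_per_mb", "occupied_per_mb"])
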