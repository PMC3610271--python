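"""Synthetic genomes, binding sites, ChIP tags, histone tracks and
expression tables with known ground truth.

The generator emulates the statistical structure of a transcription-factor
ChIP-seq experiment over a small genome: motif instances planted in random
sequence, site occupancy exponential in the matrix score, one sequenced
fragment per binding event spanning the site with a + tag at the fragment
start and a - tag at its last base, geometric PCR duplication, uniform
background tags, piecewise-constant Poisson histone tracks with planted
rich/poor segments, and genes with regulated / non-regulated expression
classes.  Every output is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenomeTable, GeneRecord, TagCollection
from .pwm_model import WeightMatrix, consensus_frequencies, revcomp, encode, BASES

NFI_CONSENSUS = "TTGGCNNNNNGCCAA"


@dataclass
class SimulationParams:
    """Study conditions for the synthetic experiment.

    The fragment model defaults to mono-nucleosome-sized protected DNA
    (mean 180 bp, sd 40, min 100); ``sequencing_insert_preset`` switches to
    the ~260 bp sequenced-insert alternative.  ``background_rate`` is the
    genome-wide average tag density of the emulated experiment (~1 tag per
    1204 bp) and ``dup_prob`` reproduces its ~2.9 tags-per-position PCR
    multiplicity.  Occupancy is Poisson with mean
    ``base_rate * exp(occupancy_slope * (score - score_low))``.
    """

    genome_length: int = 2_000_000
    n_chroms: int = 2
    seed: int = 0
    n_planted_sites: int = 500
    site_min_spacing: int = 500           # distinct binding loci; > tag-attribution reach
    score_range: tuple = (12.0, 19.5)     # native log2-odds units of the matrix
    occupancy_slope: float = 0.4          # per score unit, natural-log scale
    base_rate: float = 5.0                # expected fragments at score_low
    background_rate: float = 1.0 / 1204.0  # tags per bp
    frag_mean: float = 180.0
    frag_sd: float = 40.0
    frag_min: int = 100
    dup_prob: float = 0.65                # geometric extra-copy probability
    histone_rich_rate: float = 0.02       # tags per bp in rich segments
    histone_poor_rate: float = 0.001
    segment_length_mean: int = 50_000
    segment_length_min: int = 20_000      # chromatin domains are tens of kb

    def __post_init__(self):
        if not self.histone_rich_rate >= self.histone_poor_rate >= 0:
            raise ValueError("need rich_rate >= poor_rate >= 0")
        if self.frag_min <= 0:
            raise ValueError("frag_min must be > 0")
        if not 0 <= self.dup_prob < 1:
            raise ValueError("dup_prob must be in [0, 1)")

    def sequencing_insert_preset(self) -> "SimulationParams":
        import dataclasses
        return dataclasses.replace(self, frag_mean=260.0, frag_sd=60.0, frag_min=120)


def nfi_like_frequencies(strength: float = 0.95) -> np.ndarray:
    """Frequency matrix of the palindromic NFI-style motif
    TTGGC(N)5GCCAA: consensus bases at ``strength`` (the published logo's
    flank positions are near-saturated), spacer uniform."""
    return consensus_frequencies(NFI_CONSENSUS, strength=strength)


def nfi_like_matrix(strength: float = 0.95) -> WeightMatrix:
    return WeightMatrix.from_frequencies(nfi_like_frequencies(strength),
                                         name="nfi-like")


def _chrom_layout(params: SimulationParams):
    size = params.genome_length // params.n_chroms
    return [(f"chr{i+1}", size) for i in range(params.n_chroms)]


def _sample_site(rng, freqs, matrix, lo, hi, max_tries=1000):
    L = freqs.shape[1]
    cols = np.arange(L)
    ext = matrix.extended()
    for _ in range(max_tries):
        codes = np.array([rng.choice(4, p=freqs[:, j]) for j in range(L)])
        score = float(ext[codes, cols].sum())
        if lo <= score <= hi:
            return "".join(BASES[c] for c in codes), score
    raise RuntimeError("could not sample a site within score_range")


def make_genome(params: SimulationParams, freqs: np.ndarray | None = None,
                seed=None):
    """Random uniform-base genome with non-overlapping planted motif sites.

    Sites are sampled from the motif's base distribution, rejected until
    their matrix score falls in ``score_range``, placed on a random strand
    (reverse strand instances are inserted as the reverse complement).
    Returns (sequences, genome_table, truth_sites).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    freqs = nfi_like_frequencies() if freqs is None else freqs
    matrix = WeightMatrix.from_frequencies(freqs)
    L = matrix.length
    layout = _chrom_layout(params)
    genome = GenomeTable(tuple(layout))
    seqs = {}
    chars = np.array(list(BASES))
    for name, size in layout:
        seqs[name] = rng.choice(chars, size=size)

    lo, hi = params.score_range
    n_per = np.bincount(rng.integers(0, len(layout), size=params.n_planted_sites),
                        minlength=len(layout))
    rows = []
    spacing = max(L, params.site_min_spacing)
    for (name, size), n_sites in zip(layout, n_per):
        if n_sites * 3 * spacing > size:
            raise ValueError("planted sites do not fit without overlap")
        occupied = []
        for _ in range(n_sites):
            for attempt in range(10000):
                pos = int(rng.integers(0, size - L))
                if all(abs(pos - q) >= spacing for q in occupied):
                    break
            else:
                raise ValueError("planted sites do not fit without overlap")
            occupied.append(pos)
            site_seq, score = _sample_site(rng, freqs, matrix, lo, hi)
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = site_seq if strand == "+" else revcomp(site_seq)
            seqs[name][pos:pos + L] = list(inserted)
            rows.append((name, pos, pos + L // 2, strand, score, True))
    truth = pd.DataFrame(rows, columns=["chrom", "pos", "center", "strand",
                                        "score", "occupied"])
    truth = truth.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    truth.attrs["motif_length"] = L
    return {n: "".join(s) for n, s in seqs.items()}, genome, truth


def _duplicate(rng, n, dup_prob):
    if dup_prob <= 0:
        return np.ones(n, dtype=np.int64)
    return rng.geometric(1.0 - dup_prob, size=n)


def make_chip_tags(truth_sites: pd.DataFrame, params: SimulationParams,
                   genome: GenomeTable, seed=None) -> TagCollection:
    """ChIP tags from planted sites plus uniform background.

    Per site, Poisson-many fragments with expected count
    ``base_rate * exp(occupancy_slope * (score - score_low))``; fragment
    lengths are Normal(frag_mean, frag_sd) floored at frag_min (and at the
    motif length), placed uniformly such that the site lies inside the
    fragment; a + tag at the fragment start, a - tag at its last base;
    every tag then receives geometric PCR copies.
    """
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    L = int(truth_sites.attrs.get("motif_length", 15))
    lo = params.score_range[0]
    rows = []
    sizes = genome.sizes
    for site in truth_sites.itertuples(index=False):
        lam = params.base_rate * np.exp(params.occupancy_slope * (site.score - lo))
        n_frag = rng.poisson(lam)
        if n_frag == 0:
            continue
        size = sizes[site.chrom]
        lens = np.maximum(
            np.round(rng.normal(params.frag_mean, params.frag_sd, size=n_frag)),
            max(params.frag_min, L),
        ).astype(np.int64)
        # fragment must contain [pos, pos+L): start in [pos+L-len, pos]
        starts = site.pos + L - lens + (rng.random(n_frag) * (lens - L + 1)).astype(np.int64)
        ends = starts + lens - 1
        plus = np.clip(starts, 0, size - 1)
        minus = np.clip(ends, 0, size - 1)
        for pos_arr, strand in ((plus, "+"), (minus, "-")):
            counts = _duplicate(rng, n_frag, params.dup_prob)
            for p, c in zip(pos_arr, counts):
                rows.append((site.chrom, int(p), strand, int(c)))
    # uniform background
    for chrom, size in genome.entries:
        n_bg = rng.poisson(params.background_rate * size)
        if n_bg == 0:
            continue
        pos = rng.integers(0, size, size=n_bg)
        strands = np.where(rng.random(n_bg) < 0.5, "+", "-")
        counts = _duplicate(rng, n_bg, params.dup_prob)
        rows.extend(zip([chrom] * n_bg, pos.tolist(), strands.tolist(),
                        counts.tolist()))
    frame = pd.DataFrame(rows, columns=TagCollection.COLUMNS) if rows else \
        pd.DataFrame(columns=TagCollection.COLUMNS)
    return TagCollection(frame, genome)


def make_histone_track(params: SimulationParams, genome: GenomeTable,
                       boundary_spec="random", mark: str = "", seed=None):
    """Piecewise-constant Poisson tag track with planted rich/poor segments.

    ``boundary_spec`` is either "random" (alternating segments with
    exponential lengths of mean ``segment_length_mean``) or a list of
    (chrom, start, end, state) tuples tiling each chromosome.  Tags are
    unstranded in origin; strands are assigned uniformly.  Returns
    (tags, segments, boundaries).
    """
    rng = np.random.default_rng(params.seed + 2 if seed is None else seed)
    lam = {"rich": params.histone_rich_rate, "poor": params.histone_poor_rate}
    seg_rows = []
    if boundary_spec == "random":
        for chrom, size in genome.entries:
            if params.histone_rich_rate == params.histone_poor_rate:
                seg_rows.append((chrom, 0, size, "poor"))
                continue
            cur = 0
            state = "rich" if rng.random() < 0.5 else "poor"
            while cur < size:
                # shifted exponential keeps the stated mean exactly
                length = params.segment_length_min + int(rng.exponential(
                    params.segment_length_mean - params.segment_length_min))
                end = min(size, cur + length)
                seg_rows.append((chrom, cur, end, state))
                state = "poor" if state == "rich" else "rich"
                cur = end
    else:
        seg_rows = [tuple(s) for s in boundary_spec]
    segments = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "state"])

    rows = []
    for seg in segments.itertuples(index=False):
        n = rng.poisson(lam[seg.state] * (seg.end - seg.start))
        if n == 0:
            continue
        pos = rng.integers(seg.start, seg.end, size=n)
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        rows.extend(zip([seg.chrom] * n, pos.tolist(), strands.tolist(), [1] * n))
    frame = pd.DataFrame(rows, columns=TagCollection.COLUMNS) if rows else \
        pd.DataFrame(columns=TagCollection.COLUMNS)
    tags = TagCollection(frame, genome)

    from .genome_segmentation import boundaries_from_segments
    boundaries = boundaries_from_segments(segments, mark=mark, genome=genome)
    return tags, segments, boundaries


def make_double_boundary_locus(params: SimulationParams, locus_size: int = 300_000,
                               domain=(100_000, 200_000), seed=None):
    """A locus whose central domain is rich in a transcribed-gene mark
    (H3K36me3-like) and poor in a silencing mark (H3K27me3-like), bracketed
    by two planted binding sites at the domain edges.

    Returns a dict with the genome table, both histone tracks with their
    truth, and the bracketing site table.
    """
    rng_seed = params.seed + 3 if seed is None else seed
    genome = GenomeTable((("locus", locus_size),))
    lo, hi = domain
    k36_spec = [("locus", 0, lo, "poor"), ("locus", lo, hi, "rich"),
                ("locus", hi, locus_size, "poor")]
    k27_spec = [("locus", 0, lo, "rich"), ("locus", lo, hi, "poor"),
                ("locus", hi, locus_size, "rich")]
    k36 = make_histone_track(params, genome, k36_spec, mark="H3K36me3",
                             seed=rng_seed)
    k27 = make_histone_track(params, genome, k27_spec, mark="H3K27me3",
                             seed=rng_seed + 1)
    sites = pd.DataFrame({"chrom": ["locus", "locus"], "pos": [lo, hi],
                          "center": [lo, hi], "strand": ["+", "-"],
                          "score": [params.score_range[1]] * 2,
                          "occupied": [True, True]})
    return {"genome": genome, "k36": k36, "k27": k27, "sites": sites}


def make_genes_expression(params: SimulationParams, genome: GenomeTable,
                          n_genes: int = 2000,
                          class_fractions=(0.15, 0.10, 0.50), seed=None):
    """Genes with random TSSs and two-condition expression with known
    regulation classes.

    wt expression ~ Uniform(2, 13); ko = wt - delta with delta drawn per
    class: up > 0.5, down < -0.5, non in (-0.05, 0.05); remaining genes get
    intermediate shifts belonging to no class.  Returns
    (genes, expr_wt, expr_ko, truth_labels).
    """
    rng = np.random.default_rng(params.seed + 4 if seed is None else seed)
    f_up, f_down, f_non = class_fractions
    genes, ids = [], []
    for i in range(n_genes):
        chrom, size = genome.entries[int(rng.integers(0, len(genome.entries)))]
        length = int(rng.integers(2000, 20000))
        start = int(rng.integers(0, max(1, size - length)))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"g{i:05d}"
        if strand == "+":
            genes.append(GeneRecord(id=gid, chrom=chrom, tss=start,
                                    tes=start + length, strand=strand))
        else:
            genes.append(GeneRecord(id=gid, chrom=chrom, tss=start + length,
                                    tes=start, strand=strand))
        ids.append(gid)
    wt = pd.Series(rng.uniform(2, 13, size=n_genes), index=ids)
    u = rng.random(n_genes)
    labels = np.where(u < f_up, "up",
                      np.where(u < f_up + f_down, "down",
                               np.where(u < f_up + f_down + f_non, "non", "other")))
    delta = np.empty(n_genes)
    for i, lab in enumerate(labels):
        if lab == "up":
            delta[i] = 0.5 + rng.exponential(0.5)
        elif lab == "down":
            delta[i] = -(0.5 + rng.exponential(0.5))
        elif lab == "non":
            delta[i] = rng.uniform(-0.049, 0.049)
        else:
            delta[i] = rng.uniform(0.06, 0.45) * (1 if rng.random() < 0.5 else -1)
    ko = wt - delta
    truth = pd.Series(labels, index=ids, name="class")
    return genes, wt, ko, truth


@dataclass
class ChipExperiment:
    params: SimulationParams
    sequences: dict
    genome: GenomeTable
    truth_sites: pd.DataFrame
    tags: TagCollection
    matrix: WeightMatrix
    frequencies: np.ndarray


def simulate_chip_experiment(params: SimulationParams, seed=None) -> ChipExperiment:
    """Genome + planted sites + ChIP tags in one call."""
    base = params.seed if seed is None else seed
    freqs = nfi_like_frequencies()
    seqs, genome, truth = make_genome(params, freqs, seed=base)
    tags = make_chip_tags(truth, params, genome, seed=base + 1)
    return ChipExperiment(params=params, sequences=seqs, genome=genome,
                          truth_sites=truth, tags=tags,
                          matrix=WeightMatrix.from_frequencies(freqs),
                          frequencies=freqs)
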