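# chiptools

Analysis toolkit for transcription-factor ChIP-seq experiments of the
single-end, tag-counting era, centred on the question of how a
sequence-specific factor (the motivating case is the NFI/CTF family in
mouse fibroblasts) relates to its predicted binding sites, to nucleosomes,
and to chromatin-domain boundaries. The package is aimed at computational
biologists who want the individual analysis stages as composable, tested
library functions with a closed synthetic-data testing loop, rather than as
a web service or a monolithic pipeline.

## What it computes

Every stage operates on deduplicatable, stranded tag 5′-end positions
(`TagCollection`), 0-based half-open coordinates throughout:

* **Peak calling** (`peak_caller`) — tags are deduplicated (one tag per
  genomic position by default), shifted 75 bp in their 5′→3′ direction,
  pooled, and counted in 600 bp sliding windows; windows with ≥ *T* tags
  become peaks, greedily accepted in descending count with a 600 bp
  vicinity exclusion so one binding site is counted once.
* **PWM model** (`pwm_model`) — additive 4×L weight-matrix scoring
  (`score = Σⱼ W[bⱼ, j]`, log-linear in binding affinity), both-strand
  genome scanning above a threshold, per-column information content
  (2 − H bits), and a one-occurrence-per-sequence EM trainer that refines
  a frequency matrix from bound sequences starting from a consensus
  string (default `TTGGCNNNNNGCCAA`).
* **Positional correlation** (`positional_correlation`) — the frequency of
  target features at signed distances from reference features, binned and
  normalized by the genome-wide average target density (so 1 = no
  enrichment). Specializations: strand cross-correlation (the modal
  +/− tag distance estimates the protected-fragment length), the
  ENCODE-style motif-enrichment validation of peak lists (≥4-fold
  enrichment in ≥10 % of peaks), tag attribution to predicted sites with
  a weighted log-linear fit of mean tag count against matrix score, and
  oriented TSS metaprofiles.
* **Genome segmentation** (`genome_segmentation`) — exact two-state
  (rich/poor) partition of each chromosome maximizing
  `Σ capped counts − d·(rich length) − P·(switches)` with defaults
  d = 0.004 tags/bp, P = 20, count cutoff 5, solved by a linear-time
  dynamic program; emits polarity-bearing domain boundaries.
* **Boundary statistics** (`boundary_enrichment`) — nearest-site matching
  within 2.5 kb of boundaries (signed toward the modification-rich side),
  double-boundary calling between marks of opposite polarity, TSS/TES
  classification, per-chromosome random controls, one-sided exact
  binomial enrichment, nearest-distance distributions, and LAD-edge
  alignment.
* **Expression integration** (`expression_link`) — genomic-compartment
  densities, regulation classes from wt − ko expression differences
  (up > 0.5, down < −0.5, non < 0.05 in absolute value, all strict),
  11-bin expression groups, and bound-vs-unbound promoter comparison by
  Welch's t-test.
* **Synthetic data** (`synthetic_data`) — genomes with planted motif
  instances, occupancy exponential in matrix score
  (`λ = λ₀·e^{γ(s−s₀)}`), a mono-nucleosome fragment model with PCR
  duplication, piecewise-Poisson histone tracks with planted boundaries,
  and genes with known regulation classes: ground truth for every stage.

## Worked example

```python
import chiptools as ct

params = ct.SimulationParams(seed=1, genome_length=1_000_000, n_chroms=1,
                             n_planted_sites=300)
exp = ct.simulate_chip_experiment(params)

peaks = ct.run_peak_calling(exp.tags, ct.PeakCallParams(tag_threshold=6))
sites = ct.scan_genome(exp.matrix, exp.sequences, threshold=12.0)
res = ct.motif_enrichment_profile(peaks, sites)
profile, modal = ct.strand_cross_correlation(
    exp.tags.deduplicate(1), ct.CorrelationParams(bin_size=25, span=500))

track, _, _ = ct.make_histone_track(params, exp.genome, "random")
segs = ct.partition(track, ct.SegmentationParams(), exp.genome)
bnd = ct.boundaries_from_segments(segs, mark="H3K27me3", genome=exp.genome)

enr = ct.enrichment_test(4687, 148, 45)
```

prints, with the values observed on this run:

```
simulated tags: 108,441 at 30,439 positions
peaks at threshold 6: 298
predicted sites (score >= 12): 340
motif enrichment: factor 4.6, central frequency 46.0%, ENCODE pass: True
strand cross-correlation mode: 188 bp
segmentation: 23 segments, 22 boundaries (21 planted)
boundary enrichment: 148 (3.15%) vs 45 (0.96%), p = 2.42e-34
```

Reading the output: 298 of the 300 planted sites yield a peak; the peak
set passes the ENCODE motif criteria against the matrix-predicted sites;
the +/− strand tag spacing peaks at ~188 bp, one bin above the planted
180 bp mono-nucleosome fragment length; the two-state partition recovers
the planted chromatin domains; and the enrichment report reproduces, from
the published counts, the double-boundary occupancy percentages (3.15 %
observed vs 0.96 % random) with a one-sided binomial p-value.

A thin CLI mirrors the main stages
(`chiptools call-peaks | correlate | partition | scan-genome |
boundary-enrich | expression-link`); file dialects are BED6, FASTA, UCSC
chrom.sizes, tab-separated gene/expression tables (documented in the
module docstring of `chiptools.io_formats`), and a plain-text 4×L matrix
file.

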