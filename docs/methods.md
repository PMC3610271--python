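# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions a maintainer needs to know. No
empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Coordinates, tags and formats

All internal coordinates are 0-based half-open (BED-native); 1-based
dialects are converted at the IO boundary and nowhere else. A sequencing
read is reduced on input to its 5′-end position and strand (start for +,
end − 1 for −); read length is discarded because no downstream statistic
uses it. Identical (chrom, pos, strand) records accumulate a multiplicity
count; *deduplication* means capping that count (at 1 by default), which is
the standard defence against PCR jackpotting in tag-counting analyses.

## Peak calling

Model: a bound site yields sequenced fragments that cover it, so its + tag
and − tag pile-ups sit ~one fragment length apart. Shifting every tag
*s* = 75 bp in its 5′→3′ direction superimposes the two pile-ups for
~150 bp footprints; pooled tags are then counted in *W* = 600 bp windows
(wide enough to catch both ends of ~260 bp fragments), and windows with
≥ *T* tags are peak candidates. Candidates are accepted greedily in
descending tag count (ties: leftmost window first) while suppressing any
candidate whose center lies within *V* = 600 bp of an accepted center, so
one site is never reported twice. The peak center is the window midpoint
rounded down.

Candidate windows are anchored at tag positions: sliding a window right
until its left edge reaches the leftmost tag it contains loses no tags, so
an optimal window always exists in that anchored family. The acceptance
suite pins the whole procedure to an independent brute-force enumeration
with the same greedy rule on 200 random instances.

The caller uses no input-control subtraction and no p-value ranking; peak
quality is instead validated by motif enrichment (below). Peaks falling in
a repeat mask can be dropped by center position.

`mapping_summary` is plain bookkeeping: percentages of uniquely mapped
reads to one decimal (ordinary rounding). Reported percentage conventions
differ by context: tabulated co-localization percentages are truncated
toward zero at two decimals (this is the convention the published
counts/percentage pairs satisfy), while in-text match fractions are rounded
at one decimal. Both helpers (`truncate_pct`, `round_pct`) are exported.

## Weight-matrix model

The matrix is additive over positions in whatever score units the supplied matrix
file carries; thresholds are meaningful only on the native scale of the
supplied matrix. `N` scores as the column mean, a neutral choice so
assembly gaps neither create nor destroy above-threshold sites. Scanning
evaluates both strands of every window; when both orientations of one
window clear the threshold (the motif here is dyad-symmetric) only the
higher-scoring strand is kept, ties to +, so a palindromic locus is one
site, not two.

### EM training

`train_matrix_em` fits a one-occurrence-per-sequence (OOPS) model: each
sequence contains exactly one motif instance at a uniformly distributed
(start, strand) against a 0-order background estimated from the input
base composition. The E-step computes the posterior over placements under
the current frequency matrix; the M-step re-estimates frequencies from
expected base counts with a pseudocount of 0.5 per base (the smoothing a
Dirichlet(1.5) prior induces; published descriptions of the procedure do not state one).
The recorded objective (observed-data log-likelihood plus the Dirichlet
term) is non-decreasing — asserted by a test. Convergence is a maximum
per-entry frequency change below `tol` (default 1e-4). The initializer is
a consensus string at 0.7 consensus-base probability; the default NFI-style
consensus is the palindromic 15-mer `TTGGCNNNNNGCCAA` (two briefer variants
of this consensus circulate; the palindromic form is the one consistent
with the motif's dyad symmetry and with training from both strands).

## Positional correlation

For references *r* and targets *t* on the same genome, the engine
accumulates capped target multiplicities into bins of the signed distance
*t − r* (sign flipped for −-oriented references when orientation-aware) and
normalizes: `value = (bin count / n_ref / bin) / (total targets / genome
length)`, so uniform targets give a flat profile of 1. The genome length
in the denominator is the full assembly length from the chromosome table;
a mappable-length override is a caller decision (pass a reduced
`GenomeTable`). Distance bins are half-open `[k·b, (k+1)·b)`: a distance of
exactly 0 falls in the first positive bin. Multiplicities of both
reference and target are capped (default 10) so PCR jackpot positions
cannot dominate a profile; repeat-masked targets can be removed before
correlation.

Strand cross-correlation is `correlate(+ tags, − tags)`; its modal positive
distance estimates the protected-fragment (footprint) length because
single-end reads from opposite fragment ends map to opposite strands.

Motif-enrichment validation reports, per 300 bp distance window, the
fraction of peaks with ≥ 1 predicted site (center-to-center distance), the
central frequency (±150 bp), and the enrichment factor over the mean flank
frequency at |d| ∈ [3, 10] kb — flanks chosen where such profiles have
visibly flattened; the published figure does not print a definition. The
ENCODE rule (factor ≥ 4 and frequency ≥ 10 %) is returned as a flag.

Tag attribution: + tags go to the closest predicted-site center at or
downstream within < 200 bp, − tags to the closest at or upstream; each tag
is assigned at most once, a tag exactly at a center at distance 0. Mean
attributed count per unit-width score class is fitted as
`log(mean) ~ class midpoint` by weighted least squares (weights = sites
per class, natural-log scale, classes with zero mean omitted), so the
fitted slope estimates the exponential score-occupancy coefficient γ.

## Two-state segmentation

Objective: choose rich segments maximizing
`Σ capped counts in rich − d·(total rich bp) − P·(state switches)`, with
chromosome ends fixed poor so every rich segment pays 2 P. This is the
penalized maximal-scoring-segment formulation implied by the published
parameter roles (count density threshold d = 0.004/bp, transition penalty
P = 20, count cutoff 5); the original tool's algorithm is not publicly
specified, so the implementation is pinned instead to exhaustive enumeration
oracles on small instances. An optimal rich segment begins and ends on tag
positions (trimming tag-free margins strictly improves the objective),
which reduces the search to tag positions; a running-maximum linear DP
then finds the exact optimum with backtracking. Ties prefer no segment,
then the shorter (later-starting) segment. Strand is ignored — histone
tags are not footprint-oriented here.

Boundaries are the poor↔rich transition points: the left edge of a rich
segment has polarity `+` (rich side right), the right edge `-`;
chromosome-end edges are not boundaries.

Detectability under the defaults: absorbing a poor gap of length *g*
between two rich segments changes the objective by
`2P − (d − λ_poor)·g`, so gaps shorter than `2P/(d − λ_poor)` ≈ 13.3 kb at
the default rates are absorbed by *any* exact optimizer and their
boundaries are unrecoverable. The synthetic track generator therefore
plants domains of at least 20 kb (below).

## Boundary statistics

Each boundary is matched to its nearest site within a closed 2.5 kb
radius; the signed distance is positive toward the modification-rich side
(a site exactly at the boundary counts as rich-side). The same 2.5 kb
radius is used for boundary–boundary co-localization (double boundaries:
nearest opposite-polarity partner, one-to-one greedy by distance) and for
TSS/TES classification (TSS precedence) — the published description states the radius
only for site matching, so one consistent value is used everywhere and is
exposed as a parameter.

Random controls draw, per chromosome, the same number of uniform positions
as the template sites (assembly gaps are not excluded by default; an
exclusion mask can be applied by the caller). Enrichment is the one-sided
exact binomial `P(Binomial(n, p₀) ≥ k_obs)` with p₀ estimated from the
control; a zero-match control gets the continuity floor p₀ = 0.5/n and is
flagged. The control may pool several random draws (`control_trials`):
with a single size-n control the plug-in p₀ carries the control's full
sampling variance, roughly doubling the variance of `k_obs − n·p₀` and
making the p-value anti-conservative, so calibration experiments use a
50-fold control; single-draw reports remain available for compatibility
with the published table layout. The null-calibration experiment also
places boundaries on a jittered grid: at high boundary density, uniform
placement lets match windows overlap, correlating the per-boundary
Bernoullis and voiding the binomial model itself.

LAD alignment orients each LAD edge lamina→interior, so positive profile
distances point into the lamin-poor interior; the side summary counts
matches on either side within the radius.

## Expression integration

Compartment precedence (5′UTR > 3′UTR > coding exon > intron > 5 kb
upstream > 5 kb downstream > intergenic) makes the compartments a genome
partition so each feature is counted exactly once; when the annotation
has no exon/UTR substructure the whole gene body falls to "intron".
Regulation classes use wt − ko on the array log scale with strict
thresholds (up > 0.5, down < −0.5, non |Δ| < 0.05 — the absolute-difference
rule; a relative-percentage rule is a flag away). "Bound" genes have ≥ 1
peak center in the closed 5 kb window 5′ of the TSS, strand-aware; group
means are compared by the two-tailed Welch t-test (scipy), verified
against the closed form. Expression groups are the conventional 11 bins
(<3, 3–4, …, 11–12, >12), half-open on the left.

## Synthetic data generator

The generator emulates the statistical structure of the motivating
experiment, not its sequence content:

* **Genome/sites** — i.i.d. uniform bases; motif instances sampled from
  the NFI-style frequency matrix (consensus bases at 0.95 — the published
  motif's flank positions are near-saturated, and a softer motif would
  make matrix recovery at the tested sample sizes impossible for any
  estimator because the placement posterior no longer concentrates),
  rejection-sampled into the score range (12, 19.5) in native log2-odds
  units, placed on random strands at least 500 bp apart. The spacing keeps
  distinct "binding loci" farther apart than the 200 bp tag-attribution
  reach; without it, closest-site attribution transfers tags between
  neighbouring sites and biases the recovered occupancy slope.
* **ChIP tags** — per site, Poisson-many fragments with mean
  `λ₀·e^{γ(s−s₀)}` (λ₀ = 5, γ = 0.4/score-unit: log-linear score→occupancy
  by construction); fragment lengths Normal(180, 40) floored at 100 bp
  (mono-nucleosome protected DNA; a ~260 bp sequenced-insert preset
  exists), placed uniformly subject to covering the site; + tag at the
  fragment start, − tag at its last base. Every tag gains geometric PCR
  copies (dup_prob = 0.65, matching a ~2.9 tags-per-position multiplicity);
  background tags are uniform at 1/1204 per bp (the experiment-scale
  average tag density).
* **Histone tracks** — alternating rich/poor segments with lengths
  20 kb + Exp(30 kb) (mean 50 kb; the 20 kb floor keeps every planted
  boundary above the ~13.3 kb detectability threshold derived above),
  Poisson tags at 0.02/0.001 per bp, strands uniform. A double-boundary
  locus builder brackets a transcribed-mark-rich / silencing-mark-poor
  domain with two planted sites.
* **Genes/expression** — random TSSs, wt ~ Uniform(2, 13); ko = wt − Δ
  with Δ per class (up: 0.5 + Exp(0.5); down: the negative; non:
  Uniform(±0.049); remaining genes get intermediate shifts belonging to
  no class).

Everything is deterministic given the seed. What the generator does *not*
emulate: real genome sequence composition and repeats, mappability,
chromatin-state-dependent background, input-control structure, indirect
(tethered) binding, and probe-level microarray noise. Passing recovery
tests therefore demonstrate correctness of the estimators under the
stated generative models, not performance on real libraries.

## Problem sizes and tolerances

The acceptance computations use 1–2 Mb synthetic genomes with 300–500
planted sites, ten 2 Mb histone tracks, five (three in the script) EM
replicates of 500 × 200-mers, and 500 null-calibration replicates — sizes
at which every recovery statistic is stable across seeds while the whole
suite stays in the low minutes on one core. Recovery criteria: footprint
mode within one 25 bp bin of the planted 180 bp; ≥ 90 % of planted
boundaries within 500 bp; occupancy slope within 10 % of γ (the residual
~3 % bias is score-class midpoint discretization); EM frequency matrix
within 0.05 per informative column; regulation labels exact. Floating-point
ties at class thresholds are avoided by construction (strict inequalities,
dyadic test values).
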