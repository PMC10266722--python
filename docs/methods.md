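# Methods

This note records the models, conventions and numerical choices behind
chromspace, and what the synthetic-data tests do and do not establish.

## Coordinates and genome model

All coordinates are 0-based, half-open, everywhere: fragment intervals,
promoter TSSs (a single anchoring base), bedGraph I/O, and matrix windows.
A genome is an ordered chromosome-size table; per-base signal is stored as
one float64 array per chromosome. bedGraph output merges equal-valued runs,
omits zero runs, writes values with `repr` (so finite decimals round-trip
exactly), and carries the calibration mode in a leading comment.

## Coverage and calibration

Pileup counts, at each base, the number of fragments whose half-open
interval contains it; the track total therefore equals the summed fragment
lengths exactly, which the tests assert. Whole-fragment coverage (not
cut-site or midpoint counting) is used; a midpoint mode could be added
behind the same interface.

Two calibrations are supported. *Spike* multiplies the raw track by
`C / N_spike`, where `N_spike` is the sample's spike-genome fragment count
and `C` defaults to 10,000 (a named configuration constant, not a
hard-coded value). Spike fragments are assumed already excluded from the
experimental pileup — they map to a different genome. *Normcount* rescales
each base's fraction of total counts by a reference length (the genome
length by default), so uniform coverage reads 1 everywhere; the operation
is idempotent and total-preserving, and both properties are tested.

## TSS matrices

The window `[TSS − upstream, TSS + downstream)` is taken in transcriptional
orientation: for a minus-strand promoter, oriented offset *o* maps to
genomic base `TSS − o`, so "downstream" runs toward smaller coordinates and
minus-strand rows come out reversed. Bin values are per-base means within
10-bp bins (mean, not sum, matching the default of the widely used matrix
tools; sum is available as a parameter). Edge policy: windows truncated at
a chromosome end contribute only their covered bases; bins entirely outside
are NaN and excluded from means. A consequence worth knowing: the identity
`region_sum = bin_size × Σ bins` holds only for fully covered windows,
because truncated bins average over fewer than `bin_size` bases.

K-means clustering runs on raw matrix rows (Euclidean, 10 restarts, fixed
seed; NaN bins enter as 0). Clusters are relabeled I…k by descending mean
signal so names are stable across seeds and datasets; an all-identical-rows
matrix degenerates to a single cluster with a warning. Cluster assignments
are applied to other matrices purely by promoter ID, which is how a
clustering learned on one antibody's data orders another's.

## Promoter spacing

"Upstream" is relative to the focal promoter's own strand: the neighbor of
a plus-strand promoter is the promoter with the largest TSS strictly below
its own on that chromosome; for a minus-strand promoter, the smallest TSS
strictly above. This is the only reading under which an opposite-strand
upstream neighbor is head-to-head, i.e. divergent. Distance is TSS-to-TSS.
Ties (two equidistant upstream promoters, necessarily sharing a TSS on
opposite strands) resolve to the opposite-strand candidate, else the
lexicographically smaller ID. Promoters with no upstream neighbor on their
chromosome are annotated `none` and excluded from distance-stratified
analyses; the search never crosses chromosome boundaries. The implementation
is checked against an all-pairs brute-force oracle on hundreds of random
instances, plus translation and mirror/strand-flip invariance.

## Distance-response statistics

The moving-median curve ranks promoters by distance (descending, ties by
ID) and slides a window of `⌊n/10⌋` promoters, forced odd by subtracting 1,
so the focal promoter sits between two equal half-windows (1,697 and 848
for n = 16,972). Each full window contributes one point: median distance
versus median (or mean) signal; incomplete edge windows are dropped. The
signal statistic is a parameter because accessibility-style analyses use
the median while torsion-style analyses conventionally use the mean; the
distance coordinate is always the median.

The stratified comparison splits promoters at a distance threshold
(default 2 kb) and compares treated versus control within each stratum by a
two-sided Mann–Whitney U test — a rank test is the natural companion to a
median summary; no multiple-testing correction is applied at this level.

Outlier filtering is single-pass with strict `>`: mean and SD are computed
once from the full input (sample SD, ddof = 1), and values above
`mean + k·SD` (k = 64 by default) are removed and reported with z-scores.
Explicit mean/SD overrides are accepted for the case where the moments come
from a larger or prior dataset. The removal test is implemented as a direct
comparison against `mean + k·SD` rather than a z-score inequality so the
boundary case (a value exactly at the cut, which must survive) is decided
deterministically in floating point.

The switch point between two curves on the same ranking is the largest
distance of the longest suffix (toward small distances) on which the first
curve strictly exceeds the second — i.e. where consistent dominance begins.
Identical curves yield no switch; uniform dominance yields the maximum
shared distance.

## Fold-change profiles and quintiles

Profiles divide per-bin *means* (treated over control) — means first, then
one ratio per bin; the all-rows profile is therefore the ratio of averaged
stratum numerators and denominators, not a weighted average of stratum
ratios, and the tests assert that identity on equal-size strata. No
pseudocount is used; control-zero bins propagate as NaN gaps. Expression
quintiles are contiguous fifths of the descending expression ranking
(ties by ID), sizes as equal as possible with remainders to the top
quintiles — so the assignment is deterministic and invariant under adding
a constant to all values. `log10(x + 1)` is provided strictly as a display
transform and never feeds the ranking.

## Synthetic data

The generator's defaults encode the study conditions the analysis targets:

* **Spacing law**: lognormal gaps, meanlog 7.381, sdlog 1.868, clipped to
  [100 bp, 30 kb]. The parameters were solved so that ~40% of gaps fall
  below 1 kb and ~55% below 2 kb, the proportions reported for the fly
  promoter catalogue (6,788/16,972 and 9,288/16,972); tail clipping bounds
  the genome footprint without moving those sub-2-kb quantiles.
* **Strand assignment** works on consecutive promoter pairs: a pair is
  divergent `(−,+)` with probability q, else tandem. Counting divergent
  links per pair gives the realized divergent fraction
  `f = q + (1−q)²/4` (tandem pairs split evenly between `(+,+)` and
  `(−,−)`), so `q = 2√f − 1` for f ≥ 1/4; below 1/4, q = 0 and the tandem
  direction balance p solves `p(1−p) = f`. Orientation is thereby
  independent of gap length, so the requested fraction holds at every
  distance cutoff — verified binomially at 3 standard errors.
* **Fragments**: per-promoter counts are negative-binomial (size
  parameter `noise_dispersion`, default 10 — overdispersion keeps rank
  tests honest) around rates set by a baseline or three planted class
  levels, multiplied by `divergent_close_boost` for divergent promoters
  closer than `distance_cutoff` (default 1 kb). Fragment centers are
  normal around `TSS + downstream_shift` (defaults 100 bp and SD 60 bp,
  oriented), lengths uniform in [50, 300] bp (sub-nucleosomal to
  mono-nucleosomal), plus a 5% uniform background. Expected totals are
  scaled to `n_total`; the spike count is carried verbatim.
* **Expression**: lognormal per orientation group,
  `median · exp(dispersion · Z)`, with group medians defaulting to 210.3
  (divergent) and 34.5 (tandem); dispersion 0 collapses to the exact
  medians. Exact zeros are available via `zero_fraction` but default off
  because they bias the realized median away from its target.
* **Torsion**: a low uniform background plus signal in the 200 bp upstream
  of each TSS, multiplied by `close_pair_enrichment` for promoters with an
  upstream neighbor below 1 kb, with per-base gamma noise.

What the generator does *not* emulate: sequence content (GC, G-quadruplex
motifs), mappability, replicate-level batch structure, chromosome-scale
covariates, or correlated noise between neighboring promoters beyond the
physical overlap of their fragment windows. Passing tests therefore show
that the statistics recover planted effects under honest counting noise —
not that real libraries are free of the confounders listed above.

One real confounder *is* present in the generated data and matters for
interpretation: promoter windows physically overlap their neighbors'
fragments when gaps are short. This inflates the apparent signal of any
promoter with a close neighbor — which is precisely why mean-ratio
recovery of a planted boost is tested on a spacing law with well-separated
modes (close pairs at ~800 bp, everything else ~10 kb, "distant" meaning
isolated on both sides), while the study-scale recovery checks use the
realistic spacing law and median-based statistics, which tolerate the
contaminated minority. For the same reason the planted-class clustering
check uses wide fixed spacing (20 kb) and low overdispersion: k-means with
Euclidean distance genuinely fails to separate 5×-spaced rate classes once
multiplicative noise at the top class rivals the gap between the lower
classes, and that failure mode is a property of the method, not a bug.

## Pipeline

Stages (tracks → spacing → matrices → clustering → distance statistics →
profiles) communicate through files under the run directory, so each stage
is independently testable and a run can resume from completed outputs.
Replicate tracks are averaged per condition after spike calibration. The
summary JSON records all parameters, SHA-256 checksums of inputs and
outputs, and is byte-stable across reruns with the same seeds (matrix
exports write gzip with a zeroed timestamp for exactly this reason). The
demo generates four conditions — control, a no-effect treatment, and 1.5×
and 3× divergent-close boosts — with different spike counts and library
sizes scaled proportionally, so spike calibration is exercised
non-trivially.

## Problem sizes

Defaults in the test suite were chosen to keep the full run comfortably
interactive: oracle-equivalence tests use genomes up to 10 kb and promoter
sets up to a few hundred across 100 random instances per operation;
planted-effect recovery uses 5,000 promoters × 2 conditions × 20 seeds
(~150,000 fragments each); the demo test uses 300 promoters. The full
suite completes in under two minutes on one CPU.

## Known limitations

* Nearest-neighbor search is within-chromosome only; promoters at
  chromosome ends get no annotation rather than a censored distance.
* The switch-point rule (longest dominance suffix) localizes a single
  transition; it is not a changepoint model and reports nothing about
  uncertainty.
* Fold-change profiles with empty or control-zero bins propagate gaps
  rather than imputing; downstream plotting must tolerate NaN.
* k-means on raw signal favors splitting high-variance, high-signal
  clusters (see above); log-transforming rows before clustering is a
  reasonable variant not currently exposed.
* bigwig import/export is not provided; tracks are bedGraph-only.
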