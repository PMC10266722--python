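# chromspace

Downstream analysis of chromatin-profiling fragment data (CUT&Tag, CUTAC and
related tagmentation assays) organized around one question: **how does
promoter-proximal signal depend on the distance and relative orientation of
neighboring promoters?** Anthracycline-class drugs disrupt chromatin most
strongly at closely spaced, divergently oriented promoter pairs; this package
provides the full analysis stack needed to quantify that kind of effect, and a
synthetic-data generator that plants such effects so every stage can be tested
without sequencing data.

It is aimed at computational biologists who have per-sample fragment intervals
(BED), spike-in fragment counts, a TSS-anchored promoter table, and optionally
per-gene expression values and a torsion (psoralen-intercalation) track.

## What it computes

**Calibrated coverage.** Per-base pileup of fragment intervals, then either
spike-in calibration,

```
scaled(x) = pileup(x) · C / N_spike        (C = 10,000 by default)
```

or normalized counts,

```
norm(x) = pileup(x) / Σ pileup · L_ref
```

so that uniformly distributed coverage reads exactly 1 at every base.

**TSS matrices and clustering.** Strand-oriented matrices of mean signal in
10-bp bins around each TSS (default ±2,500 bp), k-means clustering of
promoters (k = 3 by default) with clusters relabeled I…k by descending mean
signal, cluster-ordered exports, and mean profiles.

**Promoter spacing.** For every promoter, the nearest promoter upstream *in
its own transcriptional sense*, the TSS-to-TSS distance d, and the orientation
call: **divergent** if the neighbor is on the opposite strand (head-to-head),
**tandem** if on the same strand.

**Distance-response statistics.** Promoter-proximal signal (sum over
[TSS−100, TSS+500)) as a function of d via a decile moving median: promoters
are ranked by d and a window of ⌊n/10⌋ promoters (forced odd, e.g. 1,697 with
848-promoter half-windows for a 16,972-promoter catalogue) slides over the
ranking, pairing the window median of d with the window median of signal.
Also: medians split at d = 2 kb with a two-sided Mann–Whitney U comparison
between conditions, upstream-window sums for torsion tracks with a 64-SD
outlier filter, and localization of the distance where one condition's curve
starts to dominate another's.

**Differential profiles.** Per-bin treated/control ratios of mean profiles
(linear or log2, no pseudocount), split by orientation and by descending
expression quintiles Q1…Q5.

## Worked example

The one-command demo generates a 2,000-promoter, four-condition synthetic
dataset — a control, a no-effect treatment, and two treatments with a planted
accessibility boost (1.5× and 3×) at divergent promoters closer than 1 kb —
and runs the full pipeline:

```
chromspace demo --seed 1 --out chromspace_demo
```

From `chromspace_demo/run/distance_comparisons.json` (condition `acla`, the
3×-boost treatment):

```
"switch_point_bp": 959.0,
"strata": [
 {"stratum": "close", "threshold": 2000,
  "treated_median": 7116.0, "control_median": 6378.0, "p_value": 4.8e-03},
 {"stratum": "far", "threshold": 2000,
  "treated_median": 4076.0, "control_median": 5778.0, "p_value": 3.8e-40}
]
```

Reading this: the treated condition overtakes the control at ~959 bp —
within one window-span of the planted 1-kb cutoff. Promoters closer than
2 kb show significantly higher treated medians, while distant promoters show
slightly *lower* treated signal, the expected side effect of a fixed
sequencing budget being redistributed toward boosted promoters. The no-effect
condition shows no such close-distance dominance. The same run directory
contains the orientation fractions (59% divergent below 2 kb here, matching
the generator's request), the moving-median curves per condition
(`distcurve.*.tsv`), cluster assignments, torsion outlier report, and
orientation/quintile-stratified fold-change profiles.

Library use mirrors the CLI:

```python
import chromspace as cs

genome = cs.make_genome(2, 10_000_000)
proms = cs.make_promoter_table(2000, genome, divergent_fraction=0.6, seed=1)
eff = cs.EffectModel(divergent_close_boost=3.0, distance_cutoff=1000, seed=2)
frags = cs.make_fragments(proms, eff, n_total=100_000, spike_count=5_000, genome=genome)
track = cs.calibrate_spike(cs.fragment_pileup(frags, genome),
                           cs.spike_scale_factor(frags.spike_count))  # factor 2.0
ann = cs.annotate_spacing(proms)
```

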