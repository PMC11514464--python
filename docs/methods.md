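# Methods

This note records the statistical procedures, the conventions chosen where
the field's tools disagree, and what the synthetic data generator does and
does not emulate.

## Interval arithmetic

Coordinates are 0-based half-open throughout (BED-native); any 1-based
input must be converted at ingestion. Merging coalesces overlapping *and
book-ended* intervals (as `bedtools merge` does by default) — base-pair
totals are unaffected. Venn partitions are computed exactly by sweeping the
union of interval boundaries per chromosome and classifying each elementary
segment by set membership; the 2^k − 1 classes are disjoint and sum to the
merged union length, which is asserted as an invariant.

Closest distances are unsigned edge-to-edge gaps, 0 on overlap, with both
chromosomal directions considered. A query on a chromosome with no
reference interval has no neighbor; it is reported as NaN, excluded from
distance distributions, and counted separately rather than given a
pseudo-distance. Note one boundary subtlety: a query *book-ended* against a
reference interval ([100,200) vs [200,300)) has gap 0 but zero shared
bases, so distance 0 does not strictly imply a ≥1 bp overlap.

Overlap and distance operations are strand-blind; strand is honored only by
profile anchoring and orientation.

## Signal tracks and profiles

A `SignalTrack` is a set of sorted, non-overlapping valued steps per
chromosome. Bases covered by no step are **missing**; under the default
`exclude_missing` policy they are dropped from every mean (a bin or window
with no covered base is NaN), and a `zero_fill` alternative treats them as
zero. Real pipelines differ silently on this point, which is why it is an
explicit parameter.

Scaled meta-region profiles rescale each region body to `body_bins`
positional bins (default 100, i.e. percent of region length) and add flanks
of exactly one region-length on each side, split into `flank_bins` bins.
When a region's length is not divisible by the bin count, the remainder
bases go to the leftmost bins — a deterministic, documented rule; other
tools interpolate instead, so numerical agreement with them is approximate
by design. Flanks clipped at chromosome ends count as missing. Minus-strand
regions are reversed *before* binning, so columns always read 5′→3′ and a
strand flip is an exact involution on the per-base vector. Anchored
profiles center fixed-width binned windows on the strand-aware 5′ end
(TSS); out-of-bounds bases are missing.

Aggregate profiles take the per-column mean or median over non-missing
entries only.

## Gene binding score and the bound call

A gene's binding score is the mean of 10 bp-window means of the
log2(ChIP/input) track over the gene body only (no flanks); the final
partial window is kept. Windows with no covered base are dropped; a gene
with no covered base at all scores NaN and is excluded from ranking. The
top `fraction` (default 0.10) of scored genes by score is flagged *bound*:
exactly `max(1, floor(fraction · n_scored))` genes, ties broken by (score
descending, gene id ascending) so the flag set is invariant to row order.
The minimum bound score is reported alongside, since it is the natural
per-antibody operating point of this rule.

## Region-randomization overlap permutation test

The observed statistic is the **count of query genes** with ≥ 1 bp overlap
with the merged region set (element count, not base pairs). The null is
generated by randomizing the region set `n_perm` times (default 1000):
each region keeps its length and is placed uniformly over all feasible
genome positions — the chromosome is drawn with probability proportional to
its number of valid start positions, then the start is uniform among them.
Randomized regions may overlap one another; no chromosome matching and no
assembly-gap masking is applied (rejection sampling would bias region sets
covering a substantial genome fraction, and a toy genome has no gaps).

The test is one-sided in the direction of the observed deviation from the
null mean. The empirical p-value uses the add-one convention,
`p = (#{at least as extreme} + 1)/(n_perm + 1)`, so its floor is
`1/(n_perm + 1)` — 0.001 at 1000 randomizations, the value printed when the
observation beats every randomization. `Z = (obs − mean)/sd` (sample sd);
when the null is degenerate the Z-score is reported as missing with a
warning while p remains valid. The one-sided α = 0.05 quantile of the null
is returned as the significance line for randomization histograms.

Calibration and power are part of the test suite: under an independence
null the rejection rate at α = 0.05 stays inside the exact binomial 99%
interval over 200 simulated datasets, and a planted enrichment (60% of
downregulated genes inside domains covering 15% of the genome) is detected
in ≥ 19/20 seeds.

## Distances, KS tests, multiple testing

Distance distributions are presentational: the first class is exactly 0
(overlapping), the following classes are half-open `(lo, hi]` with default
edges 0, 10 kb, 100 kb, 1 Mb and a final open class above the last edge.
KS tests always run on the **raw** distances, never the binned counts. The
two-sample two-sided KS test uses the exact null distribution of D when
both samples have ≤ 20 observations (equivalent to exhaustive label
permutation for tie-free data, which the test suite verifies by full
enumeration at n ≤ 8) and the asymptotic formula otherwise. Families of KS
p-values are adjusted with the Hochberg step-up procedure,
`adj(i) = min_{j≥i} (m − j + 1) p_(j)` capped at 1; in the pipeline the
family is all KS tests of the distances stage.

## Expression thresholds

Each rule sits on a deliberate side of its boundary, and each boundary is
unit-tested at the exact value:

| rule | convention |
| --- | --- |
| low-count filter | expected counts **> 5** (strict) in **all** libraries |
| expressed | FPKM **≥ 0.5** (inclusive) in **all** replicates |
| DEG, expression gate | CPM **≥ 10** (inclusive) in **≥ 1** library |
| DEG, effect size | \|log2FC\| **> 1.5** (strict) |
| DEG, significance | p **< 0.05** (strict) |

The differential-expression model fit itself is out of scope; the DE table
(gene, log2FC, p, per-library CPM) is an input contract.

## ChIP-qPCR

Batch normalization divides each %input value by the mean %input of that
locus across all samples of the same biological replicate, making the
per-group mean exactly 1 and removing per-batch scale. IgG control rows are
excluded from the group mean by default (they measure background, not
scale) but are themselves normalized; this is configurable. Fold enrichment
is the per-technical-replicate specific/IgG ratio, summarized as mean ± sd
with the sample (n−1) convention. A two-tailed, two-sample, equal-variance
t-test helper compares normalized values between samples.

## Synthetic data

The generator's defaults encode the study conditions this pipeline is
built for: 3 chromosomes × 10 Mb; broad domains drawn uniform 1–3 Mb long,
placed without self-overlap until they cover 15% of the genome (the final
domain is shortened to land on the target, keeping realized coverage well
inside ±2 points); 500 non-overlapping genes of uniform 2–20 kb; 215
differentially expressed genes split 80 up / 135 down, with 60% of the
downregulated ones planted fully inside domains and the rest strictly
outside; log2-ratio step tracks (100 bp steps) at +1.0 inside domains and
−0.5 outside with Gaussian noise of sd 0.3; a second "knockout" domain set
re-drawn with 60% of its domains centred on downregulated genes, emulating
relocalization toward deregulated genes; a cLAD-like broad set (20%
coverage) placed independently; and a qPCR table with per-replicate
log-normal batch factors and a 3× knockout effect. Gene lengths, step width
and noise level are desk-scale choices a practitioner would call
realistic for a toy genome; they are configurable but the defaults are the
tested conditions.

Everything is a pure function of (config, seed): fixtures are byte-identical
across reruns, and the planted parameters (domain coverage, DEG fractions,
plateau height) are recovered from the emitted files by the pipeline's own
operations in the test suite.

What the generator does **not** emulate: mappability and assembly gaps, GC
or copy-number bias, read-level noise (no FASTQ/BAM), correlated
replicates, isoform structure, or the empirical length/spacing
distributions of real domains. Passing tests therefore demonstrate the
correctness and calibration of the *procedures*, not biological claims
about any real dataset.

## Problem sizes

The default test and acceptance runs use toy genomes (1–20 kb chromosomes
for brute-force oracle comparisons, 3 × 1 Mb for calibration, 3 × 10 Mb for
planted-effect recovery), 200 permutations for repeated-simulation checks
and 1000 where a single test's p-floor matters. These sizes keep exhaustive
per-base oracles exact and the whole suite fast on one core; all operations
accept genome-scale inputs, with runtimes dominated by per-gene window
means.

## Known limitations

- Interval names/strands are dropped by `merge_intervals` (merged regions
  are anonymous unions, as in `bedtools merge`).
- The scaled-profile binning rule (remainder to leftmost bins) is this
  package's own; tools that interpolate will differ in the last decimal.
- The randomization null does not support masking or per-chromosome
  constraints; studies needing GC- or mask-aware nulls should use a
  dedicated randomization framework.
- KS p-values with heavily tied samples (many exact-zero distances) rely on
  scipy's handling of ties; the exact method assumes continuity, so for
  tie-rich data the asymptotic p is used above n = 20 and should be read as
  approximate.
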