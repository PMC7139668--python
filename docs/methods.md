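# Methods

`cistrokit` re-implements, as a tested and reusable pipeline, the
integrative cistrome analysis used to characterize a nuclear receptor
(NR2F2/COUP-TFII) inside the ERα regulatory program of luminal A breast
cancer cells: peak-set occupancy partitioning, summit-centered signal
quantification, known-motif enrichment, chromatin-loop stratification,
super-enhancer mother/daughter occupancy, fold-change/FDR differential
expression filtering, and expression-stratified survival comparison.  The
package ships a synthetic-data module that generates every input class
with constructed ground truth, so each analysis stage can be validated
end-to-end against quantities that are exact by design.

## Coordinates and overlap semantics

All coordinates are 0-based half-open (BED convention); `[0, 10)` and
`[10, 20)` do not overlap.  The occupancy partition classifies each peak
of set A as *shared* iff it overlaps ≥ 1 peak of set B by at least
`min_overlap` bases (default 1 bp).  The classification is binary per
peak: a peak overlapping several partners counts once, which matches the
fraction-of-peaks semantics of Venn-style cistrome comparisons; no
read-count (binding-affinity) differential is computed.  An optional
exclusion BED (artifact/blacklist regions) is subtracted before
partitioning.  The overlap engine is interval-tree based and is checked
in the test-suite against an all-pairs O(n²) oracle over randomized
instances.

## Summit windows, tag density and RPKM

A peak summit is the base of maximal signal; BED inputs without an
explicit summit use the interval midpoint.  The summit-inclusive window
`[summit − f, summit + f + 1)` spans `2f + 1` bp and is used for the
single-window RPKM count (101 bp at the default `f = 50`):

    RPKM = count / (window_kb × library_millions),

so the value does not depend on the called peak width.  Binned profiles
(tag density, default flank 500 bp / bin 10 bp) and heatmap matrices
(flank 1000 bp / bin 25 bp) use the window `[summit − f, summit + f)` of
width `2f`, which the default bin widths divide exactly; the
summit-inclusive odd width is retained only where a single undivided
window is needed.  Per-bin fragment counts (a fragment increments every
bin it overlaps) are averaged over peaks and scaled to a fixed library of
10⁷ fragments (configurable).  Windows left-clipped by the chromosome
start are dropped from averaging with a warning rather than partially
normalized.  Fragments are consumed as provided — no strand-shift or
fragment-extension model is applied; the synthetic generator emits
pre-extended fragments.

## Motif scanning and enrichment

Motifs are position weight matrices built from count matrices with a
pseudocount (default 0.25) and scored as log₂ odds against a background
base distribution (default uniform).  Scanning evaluates every window on
both strands and reports scores at or above the motif threshold; windows
containing N are skipped.  Sequence-level counting is ZOOPS: a sequence
counts once however many hits it contains.  "Percent of target" is
100·k/n over a sequence class, and enrichment of a target set against a
background set is the upper hypergeometric tail of drawing ≥ k_target
hit-sequences in n_target draws from the pooled urn.

The default hit threshold is the smallest score whose per-window
false-positive probability under the background model is ≤ 10⁻⁴,
computed by exact dynamic programming over the discretized per-position
score distribution (resolution 10⁻³ bits).  Scores are floor-discretized
and the threshold is padded by one grid step per motif position, so the
bound holds for the exact floating-point scores the scanner computes.
Motifs too short or too sharp to admit such a score (e.g. the 6-bp
nuclear-receptor half-site, whose consensus already has probability
≈ 2.4 × 10⁻⁴ under a uniform background) have the threshold capped at the
maximum achievable score, with a warning: the consensus still registers
as a hit, and the cap is part of the documented contract.

The packaged motif library (`data/motif_counts_synthetic.txt`) covers the
classic ERα-cofactor motifs (ERE, DR1, FOXA1, GATA3, AP-1, AP2-γ, CTCF,
NR half-site).  The matrices are synthetic, consensus-derived counts
(85 : 5 : 5 : 5 per position, uniform at degenerate positions) — adequate
for threshold calibration and fixture construction, not measured binding
data; users analyzing real sequence should substitute a curated library
via `load_motif_library(path)`.

## Loops and super-enhancer occupancy

Chromatin interactions are BEDPE anchor pairs (anchors normalized into
genome order; optional PET support column).  A peak "overlaps a loop"
when it intersects either anchor; a loop counts at most once per peak
even when both anchors are hit, which avoids inflating the high-
interaction stratum.  Peaks are stratified by loop count into ≥ 2 / 1 / 0
interaction classes, and per-stratum binding intensities (summit RPKM)
are compared pairwise with two-sided Mann–Whitney tests.

Super-enhancer constituents are consumed as BED regions labelled
`SEid:mother` / `SEid:daughter` ("mother" = pre-established constituent,
"daughter" = ligand-induced constituent); re-deriving super-enhancers
(ROSE-style stitching) is out of scope.  A region is scored positive iff
it overlaps ≥ 1 peak whose loop count reaches `min_loops` (default 1,
configurable — the alternative ≥ 2 reading is exposed as a flag), and the
per-role percent is reported at two decimals.

## Differential expression

The two-group test is a deliberately simple NB exact-style test, not an
edgeR replication: counts are scaled to the mean library size, a single
common dispersion is estimated across genes by the method of moments
(median of per-gene, per-group `(var − mean)/mean²`), and the p-value is
the exact conditional tail of one group's scaled sum given the total,
with group sums modeled as NB with size `n_g/φ`.  As φ → 0 this reduces
to the conditional binomial (Poisson two-sample) exact test, which the
suite verifies.  log₂ fold change is the mean log-CPM difference
(knockdown − control, prior count 0.5).  Multiple testing uses
Benjamini–Hochberg; a gene is "up" iff `log2fc ≥ log2(fc_min)` and
`fdr < fdr_max` (defaults 1.5 and 0.01), "down" symmetrically.  TMM
normalization, tagwise empirical-Bayes dispersion and GLMs are
intentionally absent; the fixtures are designed with margins wide enough
that any reasonable NB test recovers the constructed truth.

A preranked running-sum enrichment score (classic weighted
Kolmogorov–Smirnov statistic with leading-edge extraction) is provided
for gene-set readouts; the permutation null, NES and gene-set FDR
machinery of full GSEA are not implemented.

## Survival

Cohorts are tables of follow-up time (months), event indicator and an
expression z-score.  Patients are split at the median (ties to "low"; the
quantile is configurable — optimal-cutoff scanning is deliberately not
implemented).  Curves use the product-limit estimator (censored-only
times do not drop the curve) and groups are compared with the logrank
(Mantel–Cox) statistic — observed minus expected events summed over
distinct event times with the hypergeometric variance, referred to
χ²(1).  Both are implemented directly from the closed forms and verified
against lifelines in the test-suite.

## Synthetic data: what it emulates, and what it does not

Each generator is a pure function of (config, seed); identical inputs
reproduce identical data.  Designed fractions are realized exactly by
construction, independent of the seed:

* **Cistromes** (`mcf7_like`): 3,000 + 1,000 peaks (width 400 bp) on a
  toy chromosome, 900 constructed shared pairs with ≥ 200 bp overlap and
  all factor-specific peaks isolated by > 1 kb, giving a 90.0% shared
  fraction for the smaller set.  Fragment piles are Poisson around
  summits (means 50 shared / 10 specific, length 200 bp, jitter ± 500 bp,
  2,000 uniform background fragments), so shared-class profiles dominate
  specific-class profiles bin-by-bin.
* **Sequences** (`motif_freq`): two classes of 10,000 × 100-bp uniform-GC
  sequences carrying exactly 3,091 and 1,764 embedded GATA3 consensus
  instances (30.91% / 17.64%); every non-embedded sequence is
  rejection-sampled until it contains no hit at the scanner's threshold
  on either strand, which is what makes percent-of-target exact rather
  than approximate.
* **SE architecture** (`se_loops`): 1,250 mothers and 2,500 daughters;
  exactly 790 mothers (63.20%) and 286 daughters (11.44%) receive a peak
  joined by a loop to a distant hub anchor; 60 further mothers get a
  loop-free peak, and 150/150/200 free-standing peaks populate the
  ≥ 2/1/0 strata with stratum-dependent fragment intensity
  (means 60/30/8).
* **Counts** (`de_se_genes`): 2,000 genes × 6 + 6 samples, NB dispersion
  0.01, designed |log₂FC| = 2 for 388 down- and 524 up-regulated genes at
  baseline mean 500.  Down-regulated genes receive a higher baseline
  (≈ 2,701, solved so expected group library sizes match), because with
  pure CPM normalization an unbalanced design of this size would shift
  every null log-fold-change by ≈ 0.6 through composition bias.  With the
  balanced design the null log₂FC standard deviation is ≈ 0.09, an
  ≈ 6.4 σ margin below the 0.585 call threshold, so the designed sets are
  recovered exactly for any seed.  236 genes carry an SE-association
  flag, 99 of them among the designed DE genes.
* **Survival** (`survival_cohort`): 200 patients per arm, exponential
  baseline hazard 0.01/month, hazard ratio 3 for the low-expression
  group, uniform censoring on [0, 120] months.

The generators do **not** model read-level noise, GC bias, mappability,
copy-number structure, peak-calling uncertainty, overlapping/nested SE
units, between-gene dispersion heterogeneity, or non-proportional
hazards.  Passing the fixture-recovery tests therefore demonstrates that
the analysis operations implement their definitions exactly — not that
the pipeline is robust to the full noise structure of real ChIP-seq,
ChIA-PET or RNA-seq data.

## Numerical choices and degenerate inputs

* Ties in nearest-TSS assignment break toward the smaller genomic
  coordinate, then the lexicographically smaller gene id; peaks on
  chromosomes without a TSS map to "NA" and are logged.
* Mann–Whitney uses the exact permutation distribution when the pooled
  sample size is ≤ 12 and tie-free, otherwise the normal approximation
  with midrank tie correction and continuity correction.
* The exact conditional DE p-value sums all splits with probability ≤ the
  observed one (with a 1 + 10⁻¹² tolerance against float equality);
  p-values are clipped into (0, 1].
* Heatmap rows sort by row sum descending with ties broken by peak name;
  hierarchical heatmap ordering uses z-scaled rows, Euclidean distance,
  complete linkage and scipy's deterministic leaf order.
* Empty peak sets partition to all-"only"; an empty loop file yields
  stratum "0" for every peak and 0% SE occupancy; all-censored survival
  input is a flat curve; zero-event logrank input is an error.
* Pipeline reports are written with fixed float formatting (`%.6g`) and
  no timestamps, so re-runs with the same configuration are
  byte-identical.

## Problem sizes

The packaged fixture sizes (above) were chosen as the smallest designs
that represent every reported fraction exactly at two-decimal precision
(denominators 1,000 / 1,250 / 2,500 / 10,000) while keeping a full
pipeline run in a few seconds on a single core; the statistical
calibration check uses 1,000 null cohorts of 200 patients.
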