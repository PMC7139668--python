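# cistrokit

An integrative cistrome-analysis toolkit for regulatory genomics,
motivated by the question of how an orphan nuclear receptor
(NR2F2/COUP-TFII) participates in the ERα transcriptional program of
luminal A breast cancer cells.  It is aimed at computational biologists
who want the individual analysis steps of such a study — peak overlap
partitioning, summit-centered signal quantification, known-motif
enrichment, chromatin-loop stratification, super-enhancer occupancy,
differential-expression filtering and survival comparison — as small,
tested, composable library functions rather than a chain of one-off
shell commands, together with synthetic data whose ground truth is known
exactly.

## What it computes

* **Occupancy partition** — peaks of two factors A and B are classified
  per peak: shared iff overlapping ≥ `min_overlap` bp (0-based half-open
  arithmetic), giving the peak-fraction Venn quantities
  `|shared_A|/|A|`.
* **Tag density and RPKM** — per-bin fragment counts in summit-centered
  windows, averaged over peaks and scaled to 10⁷ fragments; and
  `RPKM = count / (window_kb × library_millions)` on the fixed
  summit ± 50 bp (101 bp) window.
* **Known-motif enrichment** — PWM log-odds scanning on both strands
  with an exact-DP threshold at per-window FPR ≤ 10⁻⁴, ZOOPS counting
  (percent of target = 100·k/n), and the upper hypergeometric tail
  P(X ≥ k_target) over the pooled target+background urn.
* **Loop stratification and SE occupancy** — per-peak counts of
  ChIA-PET-style loops touching either anchor (once per loop), the
  ≥2 / 1 / 0 interaction strata with pairwise Mann–Whitney intensity
  tests, and the percent of super-enhancer mother/daughter regions
  containing a loop-linked peak.
* **Differential expression** — a simplified NB exact-style test
  (common moment-estimated dispersion, exact conditional tail on
  library-scaled group sums), BH FDR, and the standard
  |log₂FC| ≥ log₂ 1.5, FDR < 0.01 up/down filter, plus the intersection
  with SE-associated genes and a preranked running-sum enrichment score.
* **Survival** — median split on an expression z-score, Kaplan–Meier
  product-limit curves, and the logrank (Mantel–Cox) χ²(1) test.

The `simulate` module generates all inputs with constructed ground truth
(exact overlap fractions, certified hit-free motif backgrounds, exact SE
loop fractions, designed DE genes with wide margins, configured hazard
ratios), and `pipeline`/the `cistrokit` CLI run everything end-to-end
into a deterministic report.  See `docs/methods.md` for the models,
conventions, and the limits of what the synthetic data demonstrates.

## Worked example

Run the full fixture-driven pipeline:

```sh
cistrokit all --outdir run1 --seed 7
```

`run1/report.tsv` (also echoed to stdout) contains:

```
cistrome.n_era	3000
cistrome.n_nr2f2	1000
cistrome.shared_percent_nr2f2	90
cistrome.shared_percent_era	30
cistrome.profile_center_shared	2173.11
cistrome.profile_center_only	439.904
motif.percent_of_target_only_era	17.64
motif.percent_of_target_shared	30.91
motif.enrichment_p_shared_vs_only	2.33487e-107
loops.stratum_size_0	260
loops.stratum_size_1	1226
loops.stratum_size_ge2	150
loops.se_mother_percent	63.2
loops.se_daughter_percent	11.44
loops.mw_p_ge2_vs_1	1.14907e-71
loops.mw_p_ge2_vs_0	1.43171e-64
loops.mw_p_1_vs_0	9.95447e-133
de.n_down	388
de.n_up	524
de.n_se_genes	236
de.n_se_de	99
survival.n_high	200
survival.n_low	200
survival.logrank_chi2	51.678
survival.logrank_p	6.53901e-13
```

Reading it: 90% of the smaller peak set is shared with the larger one,
and shared peaks carry ~5× the summit tag density of factor-specific
peaks (2173 vs 440 tags per 10⁷ at the summit bin).  The GATA3 motif
occurs in 30.91% of shared-class windows vs 17.64% of the
single-factor class, a strong hypergeometric enrichment.  Peaks with ≥2
loops have significantly higher RPKM than peaks with 1 or 0
(Mann–Whitney p ≪ 10⁻⁴), and 63.2% of SE mother regions vs 11.44% of
daughter regions contain a loop-linked peak.  The knockdown count matrix
yields 388 down- and 524 up-regulated genes, 99 of the 236 SE-flagged
genes change, and the low-expression arm of the cohort relapses faster
(logrank p ≈ 7 × 10⁻¹³).  Each number equals the corresponding
generator's designed truth.

Stage subcommands (`overlap`, `motif`, `loops`, `de`, `survival`) run a
single stage; `--config config.yaml` overrides thresholds
(`min_overlap`, flanks/bins, `fc_min`, `fdr_max`, `min_loops`,
`split_quantile`).  Re-running with the same configuration and seed
reproduces every output byte for byte.

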