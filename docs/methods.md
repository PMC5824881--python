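# Methods

## Seed words and site types

A mature miRNA is an RNA string read 5′→3′; its seed is nucleotides 2–8.
Target-site words are spelled in DNA on the 3′UTR sense strand:

* `word_7m8` = reverse complement of nt 2–8 (the 7mer-m8 site),
* `word_8mer` = `word_7m8` + `A` (the position-1 A is a site feature, not a
  base pair, so it is appended rather than complemented),
* `word_7a1` = `word_7m8[1:]` + `A` (the 7mer-1A site).

miRNAs with identical nt 2–8 seeds are one *family*, keyed by `word_7m8`.
Family collapsing is what makes the universe non-redundant on the miRNA
side; we emulate, but do not byte-reproduce, curated family definitions
such as TargetScan's (those can be loaded from a flat file instead).

Scanning is exhaustive left-to-right over the sense strand only; `N` and any
other non-ACGT letter never match.  Longest-site precedence keeps one
physical site one universe entry: an 8mer match yields a single 8mer hit and
suppresses the constituent 7mer-m8 at the same start and the 7mer-1A at
start+1.  Coordinates are 0-based, half-open.

### 3′-compensatory sites

The 3′-compensatory class has no single standard definition, so the rule
here is deliberately simple and documented: a 7 nt window whose pairing to
miRNA nt 2–8 shows exactly six Watson–Crick pairs plus exactly one G:U
wobble or one mismatch, together with ≥ 4 consecutive Watson–Crick pairs
between miRNA nt 13–17 and UTR sequence 1–6 nt 5′ of the window (miRNA nt
13+j opposes UTR position `start − gap − 1 − j`).  Canonical sites are never
double-typed.  Because the rule is an operational approximation, 3comp
scanning is off by default (`include_3comp=False`) and participates in
nothing unless requested.

## Gene-set enrichment

The DE table is collapsed to gene level (duplicate ids keep the smallest raw
p — the natural probeset→gene rule when several probes interrogate one
gene), then partitioned: strict inequality on p (matching the convention
"P < 0.05"), inclusive on the fold-change magnitude at the cutoff (so a
gene printed exactly at the cutoff after rounding is kept).  Signed
fold-change ratios (|r| ≥ 1, sign = direction) and log2 fold changes
interconvert exactly; ratio −1 and +1 both denote "no change" and log2fc 0
decodes to +1.

Each family × direction gives a 2×2 table of gene-level site presence
(≥ 1 site, not site counts — counts would overweight long UTRs) against set
membership over the background of all tested genes.  The background is the
intersection of the DE table with the UTR set (or the loaded site file plus
the DE genes): the universe must be what the experiment interrogated.

* Odds ratio: (a·d)/(b·c); with any zero cell the Haldane–Anscombe +0.5
  correction is applied to all four cells and the result flagged.  The
  correction affects only the reported odds ratio, never the test.
* Significance: two-sided Fisher exact test by the point-probability method
  (all tables with the observed margins whose probability is ≤ the observed
  table's, within relative tolerance 1e−7).  One two-sided p per family; the
  odds ratio's side of 1 indicates enrichment vs depletion.
* Multiplicity: Benjamini–Hochberg step-up across families, separately
  within the down and up directions (the two directions are separate
  questions and are reported as separate lists).

The cross-study overlap test is the same machinery applied to the table
(n_both, n_a−n_both, n_b−n_both, N−n_a−n_b+n_both) for two changed-gene
lists of sizes n_a, n_b sharing n_both genes in a common N-gene universe.

## Ranked-list word landscape

All genes, regardless of significance, are ranked by log2 fold change,
descending (most upregulated first; ties broken by stable input order for
reproducibility).  For word *w* and leading-set size *x*, the statistic is
the hypergeometric tail over k-mer *positions*: N = valid k-mer windows in
all UTRs, K = occurrences of *w* overall, n = windows in the leading *x*
genes, k = occurrences of *w* there.  Overlapping occurrences all count;
windows spanning a non-ACGT letter contribute neither occurrences nor
positions.  The signed score is −log10 P[X ≥ k] when the enrichment tail is
smaller, +log10 P[X ≤ k] otherwise; a word absent from all UTRs scores 0
everywhere.  Exact identity: the enrichment p at cutpoint x equals the
depletion p at cutpoint (n_genes − x) of the reversed ranking.

Default cutpoints fall every ⌈n_genes/50⌉ genes.  The Bonferroni reference
line is −log10(α / n_words) with α = 0.05 and the number of panel words as
the default denominator (one line per figure; a words × cutpoints
denominator is available).  The original landscape tool's
sequence-composition bias correction is intentionally out of scope: this is
the plain occurrence-level statistic, which is the right comparison for the
synthetic data below and close to the real tool wherever composition is
homogeneous.

## Synthetic studies

The generator emulates the data a misexpression microarray study feeds into
these analyses, with known ground truth.  Defaults are the package's
standing study conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes | 2000 | genes on the simulated platform |
| utr_len_range | 200–1500 nt | uniform UTR lengths, microarray-transcriptome scale |
| base_composition | uniform | i.i.d. background sequence |
| planted_family | miR-96 | family whose sites are planted |
| target_fraction | 0.30 | genes receiving ≥ 1 planted site |
| copies_per_target | 1 | planted sites per target gene |
| effect_log2 | −1.0 | mean log2 shift of site-bearing genes (repression) |
| noise_sd | 0.5 | per-sample Gaussian SD on the log2 scale |
| n_replicates | 5 | samples per group |
| n_decoy_families | 20 | random miRNA families with no expression effect |

Planted words (randomly 7mer-m8 or 8mer) overwrite the background sequence
at non-overlapping offsets, keeping lengths — and hence landscape position
totals — fixed.  Expression: control ~ N(0, σ²), case ~ N(δ·is_target, σ²),
log2fc = difference of group means, p from the two-sided Welch t-test
(robust to the equal-variance assumption and the standard default for small
group comparisons).  Signed ratios derive from log2fc by the exact inverse
map.  One `numpy.random.Generator` stream, seeded from the config, threads
through decoys → UTRs → expression, so a seed reproduces a run byte for
byte.

What the generator does *not* emulate: probe-level effects (RMA, batch and
block structure), correlated genes, UTR composition bias, and
conservation-filtered site universes.  Passing the recovery tests therefore
demonstrates that the statistical machinery detects a planted aggregate
signal at realistic sizes and noise — not that any particular biological
dataset will show one.

### Calibration under the permutation null

With δ = 0 the partition still produces a small "down" set (~2–3% of genes:
noise passing the thresholds).  Shuffling gene labels at that fixed set size
gives the exact permutation null for the family tests.  Two facts shape the
calibration check:

1. Family tests within one permutation replicate share a single label draw
   and are correlated, so the *replicate* is the independent unit: the
   observed P(p < 0.05) is compared with 0.05 within three binomial
   standard errors at n = 200 replicates.
2. Exact conditional tests are discrete: at these margins (set ≈ 50 genes,
   family presence ≈ 10% of 2,000 genes) the attainable p-values form ~15
   atoms and the test is conservative — its true size is ≈ 0.03–0.04, below
   the nominal 0.05, and its null p-values are *not* KS-uniform.  The
   calibration therefore additionally asserts one-sided validity
   (P(p ≤ t) ≤ t + noise on a grid of t): a correct exact test may be
   conservative but must never be anti-conservative.

## Numerical and interface choices

* Fisher exact p, hypergeometric tails, Welch t and χ² come from
  scipy/statsmodels; every one is checked in the test suite against an
  independent hand-written enumeration or direct-formula oracle (exhaustively
  for all 2×2 tables with N ≤ 40, by symmetry in the margins).
* Mendelian goodness of fit: Pearson χ², df = 2, no continuity correction,
  expected counts required ≥ 1.  On the published genotype counts this
  reproduces the printed p-values for two of the three transgenic lines
  (0.018 ≈ 0.017 and 0.40); the third line's printed 0.98 is not a 1:2:1
  Pearson χ² on its counts (exact value 0.89) — whatever test produced that
  number, it was not this one, and the discrepancy is asserted in the suite
  rather than hidden.
* ΔΔCt fold change is 2^(−ΔΔCt) with ΔΔCt the case-minus-control difference
  of (target − reference) Ct values; swapping case and control inverts the
  fold exactly.
* All output tables are tab-separated, one header line, `.` for missing
  values; reruns with identical configs are byte-identical (fixed seeds,
  stable sorts).  Enrichment rows sort by FDR within direction; ranking ties
  break by input order.
* Problem sizes in the shipped analysis and the acceptance script are the
  default study conditions above (2,000 genes, 21 families, 200 permutation
  replicates) — large enough for unambiguous recovery (planted-family FDR
  below 1e−200) while a full run stays in seconds.

## Known limitations

* The 3comp rule is an operational simplification; off by default.
* No conservation scoring: a conserved-site universe must be supplied as a
  flat file to reproduce conservation-filtered analyses.
* The landscape has no composition-bias or Markov-background correction.
* The two-study generator shares a single RNG stream seeded from study A's
  config; study B's seed field does not independently re-seed it.
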