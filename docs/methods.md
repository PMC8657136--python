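# Methods

This note documents the models, estimators and design choices behind
`dosegrade`, and what the synthetic benchmark does and does not establish.

## Study design and data model

The design is a full factorial: 3 genotypes (WT, T58A, T58I) × 7 doxycycline
doses (0, 25, 50, 100, 300, 600, 1000 ng/mL) × n replicates (default 3),
one RNA-seq count vector per sample. Counts for gene g in sample s are
modelled as negative binomial with mean μ_gs and variance
μ_gs + α_g μ_gs², where α_g is the gene-wise dispersion (squared biological
CV). NB is the standard overdispersed model for bulk RNA-seq counts and is
the distribution the synthetic generator draws from, so model and generator
are matched by construction; real data may deviate (outliers, batch
structure — see Limitations).

## Synthetic data generator

The generator is first-class, tested code: every downstream stage is
exercised against data whose ground truth is known.

- **Dose response.** Each regulated gene follows a Hill curve on the log2
  scale: log2 μ(d) = β + a · h(d), h(d) = d^s / (d^s + EC50^s). h(0) = 0 and
  h(EC50) = ½, so `a` (log2 units, drawn from `amplitude_range`, signed by
  direction) is the full-range amplitude. The default Hill slope is 2.5 —
  tet-regulated induction is steep and switch-like — which concentrates the
  response between adjacent doses and makes the 6-df dose test informative;
  a shallower slope spreads the same amplitude thinly across the curve and
  lowers power for any test.
- **Genotype effects.** Default EC50s are 150 (WT), 25 (T58A), 600 (T58I)
  ng/mL, encoding the observed sensitivity ordering: T58A responds near the
  lowest dose, T58I only at high doses. Only genes labelled differential in
  a mutant use that mutant's EC50 (plus an amplitude boost, default ×2);
  other regulated genes share the WT curve in all genotypes, so
  "differential" has a well-defined truth. A configurable fraction of
  differential genes is regulated *only* in the mutant.
- **Noise.** Gene dispersions are Gamma(shape=2, rate=20) (mean 0.1,
  BCV ≈ 32%), or pinned via `dispersion_fixed` for calibration scenarios.
  Library sizes are log-uniform over (8e6, 1.5e7) and scale the means
  multiplicatively, exercising normalization.
- **Genome.** One chromosome; genes laid end to end with 5 kb private flanks;
  strand random; background sequence is rejection-resampled until it
  contains no CACGTG, then motifs are planted so that the midpoint sits at
  the scheme's requested distance from the TSS (downstream of a + TSS, into
  the gene body for −). Because planted distances must stay below the flank,
  each gene's own motif is provably its nearest, which is what makes exact
  planted-distance recovery a meaningful test. Distances beyond the flank
  raise an error rather than silently misplace.
- **Gene sets.** Truth-enriched sets draw 80% of members from a labelled
  category (WT-regulated; T58A-differential) and the rest uniformly;
  uniform control sets calibrate specificity. Set size adapts downward for
  tiny simulations (≤ a quarter of the gene count).

All randomness descends from one seed through named `SeedSequence` spawns;
identical configs produce byte-identical output files.

## Differential expression

**Model.** Per gene, an NB log-linear GLM with one mean per
(genotype, dose) cell and log effective library size as offset. The full
(saturated) fit reduces to independent single-mean problems per cell, solved
by Newton iterations on the log mean; the residual deviance on 63 samples
with 21 cells leaves 42 df for the quasi-likelihood scale.

**Normalization.** Model offsets use median-of-ratios effective library
sizes by default. Plain column sums are available (`normalization=
"column_sum"`) but are not composition-safe: when regulation is not balanced
between up and down — the typical MYC situation — column sums become
dose-dependent, flat genes acquire an apparent dose response (~10% type-I at
nominal 5% in our mixed simulations), and true signals shrink. The
median-of-ratios factors restore null calibration (~4–5%) and recover power.
The CPM filter itself (CPM ≥ 0.95 in ≥ 3 samples, thresholds inclusive)
deliberately uses raw column-sum CPM, since it mimics a pre-normalization
abundance screen.

**Dispersion.** Gene-wise α is estimated by maximizing the Cox–Reid adjusted
profile likelihood (APL = loglik − ½ log det X'WX, which for cell means is
½ Σ_cells log Σ w) on a 40-point log-spaced grid over [1e-6, 5] with
quadratic refinement. Estimates are then replaced by a lowess trend on
average log-CPM (`trend_weight=1.0`; intermediate weights interpolate on the
log scale): the trended value enters the GLM fits, and gene-level
variability is absorbed by the QL scale instead — double-counting it in both
places would be conservative. Parameter recovery: median estimate < 0.05 on
Poisson data; within [0.2, 0.6] at true α = 0.4 (both tested).

**Tests.** Three families per gene, each a 6-df deviance comparison against
the saturated fit: (wt) WT means collapsed across dose; (t58a/t58i) the
mutant's dose profile constrained to WT's shape plus a free intercept, fitted
by per-gene IRLS (relative deviance change < 1e-8 or 100 iterations;
non-converged genes get missing p and are excluded from BH). The QL
F-statistic is (Δdev/6)/s²_g with s²_g the residual deviance scale squeezed
toward an empirical-Bayes prior: a scaled-F model fitted by moments of
log s², with the prior location a lowess trend on average log-CPM (per-gene
scales vary systematically with expression level). p-values come from
F(6, d0 + 42); BH runs within each family separately, since gene counts are
reported per family. NB deviances at 3 replicates/cell are inflated relative
to χ² (null mean Δdev ≈ 6.5–8 on 6 df); the QL scale absorbs this
multiplicatively, which is exactly why the F-ratio is calibrated where a raw
χ² LRT would not be (the `chi2` fallback exists but is anticonservative at
this depth of replication).

**Selection.** A family's flag requires q < q_max (default 0.01, strict) and
a fitted fold change ≥ min_fold (default 2, inclusive) between at least two
of the family's condition means — WT dose pairs for the WT family, all
{WT, mutant} × dose cells for a mutant family. Fitted means are floored at
0.125 CPM before ratios so zero cells cannot produce infinite fold changes.
Measured operating characteristics (2000 genes, 500 regulated at amplitude
2 log2, α = 0.2, 3 reps): recovery 0.94–0.96, FDP ≤ 0.015 across seeds;
fully null data: fraction p < 0.05 within [0.03, 0.07], no BH rejections.

## Clustering and characterization

Profiles are replicate means of log2(RPKM + 1) over the 21 conditions
(genotype-major, dose ascending). Ward linkage on Euclidean distances is cut
to exactly k = 12 flat clusters; labels are renumbered by dendrogram leaf
order, since any particular numbering is arbitrary; the partition itself is
permutation-stable (tested). Direction is classified on WT:
up iff mean RPKM(1000) > mean RPKM(0), strict inequalities, ties a third
"unchanged" category.

Characterization per cluster: % up/down, median of gene-mean RPKM, %
non-coding with a 2×2 χ² (continuity-corrected; Fisher fallback when an
expected cell < 1) against the non-regulated background, and — for gene
length and minimum TSS–E-box distance — a resampling test: B = 1000 draws of
cluster-size subsets (without replacement) from the non-regulated genes,
two-sided empirical p = 2·min(r_low+1, r_high+1)/(B+1), capped at 1. The
(r+1)/(B+1) estimator never returns 0 and is calibrated (rejection rate at
0.05 within [0.02, 0.09] under the null; tested over 200 repetitions).
"Adjusted" p-values are BH across the k clusters within each statistic;
significance at 0.05 (categorical) and 0.02 (resampling).

## E-box proximity

CACGTG is scanned exactly, case-insensitively, with overlaps; N never
matches. Because the motif is its own reverse complement, + and − alignments
at one start are one genomic position: positional statistics count it once
(`palindrome` flag retained), while `alignment_count` reports
strand-duplicated totals for comparability with aligner-based counts.
Distances are |TSS − (start+3)|, unsigned, 0-based, TSS = strand-aware 5′
gene end; the ±1 kb window is inclusive. Genes on motif-free chromosomes get
missing distance and a False flag. The scanner and the nearest-TSS
assignment (ties → lexicographically smallest gene id) are tested against
brute-force oracles.

## Set enrichment

The three selection flags map each flagged gene to exactly one Venn region
A–G (A: WT only … G: all three). All Fisher/ORA tests use the
CPM-filter-passing genes as universe — the natural "detected" background —
and sample odds ratios (inf/0 at zero cells, p unaffected). The
set-by-cluster heatmap runs both one-tailed tests per cell, keeps the
smaller tail as the cell's direction, BH-adjusts across all cells and
reports sign(direction) · −log10(p_adj). ORA is hypergeometric
over-representation per GMT set (intersected with the universe; empty
intersections are skipped and noted), BH across the collection, significant
at FDR ≤ 0.1. External lists may pass through an exact two-column ortholog
map; unmapped identifiers are dropped and counted, and a list that misses
the universe entirely is an error rather than a silent p = 1.

## Sensitivity score and preranked GSEA

Per genotype, s = |FC|_{25/0} / |FC|_{600/300} on replicate-mean RPKM with a
0.125 pseudocount, where |FC| = max(FC, 1/FC) is the fold-change magnitude —
so a gene strongly *repressed* at low dose is as "sensitive" as one strongly
induced, and the score is symmetric in regulation direction. Genes are
ranked by log2(s_T58A / s_T58I) (order-identical to the raw ratio; the log
symmetrizes the weights). High values mean the gene's response concentrates
at low doses in T58A relative to T58I.

The preranked GSEA walks the descending list (ties by gene id): hits add
|metric|^p / N_R (p = 1), misses subtract 1/(N − n_set); ES is the
maximum-magnitude deviation. Running-sum extrema can only occur at a hit (a
peak) or immediately before one (a trough), so only those candidates are
evaluated — the implementation is O(n_set) after ranking and matches a
hand-stepped oracle to 1e-12. At an exact peak/trough magnitude tie (common
for single-gene sets at the list midpoint) the extremum reached first along
the walk wins; the sign at such ties is a convention, and the
"reversal negates ES" identity holds only away from them. The null is
gene-label permutation (random same-size sets, n_perm = 1000 by default);
NES divides ES by the mean |null ES| of matching sign; p = (r+1)/(m+1)
within the same-sign null; BH across sets; the leading edge is the members
at/before a positive extremum (at/after a negative one). Permutation
p-values are uniform under a random metric (KS-tested). Selection applies
adjusted p ≤ 0.05 and |NES| ≥ 1.7, both inclusive.

## Pipeline

`RunConfig` (YAML-loadable) carries every threshold, the seed, stage toggles
and input paths; stages run in dependency order (simulate → de → cluster →
ebox → sets → gsea), each skippable so real count tables replace the
simulator. Failures abort naming the stage. The summary JSON echoes the
config, per-stage counts and a SHA-256 manifest; identical configs reproduce
identical checksums (tested). Derived RNG streams use seed, seed+1 (cluster
resampling), seed+2 (GSEA permutations).

## Problem sizes

Defaults are desk-scale by choice: 2000 genes (≈ 1/7 of a filtered mouse
transcriptome), 63 samples, genome ≈ 25 Mb, B = 1000 resamples,
1000 permutations. The statistical structure (per-gene tests, 6-df
contrasts, BH within families) is size-independent; absolute gene counts
scale with `n_genes` and `frac_regulated`.

## Known limitations

- The generator matches the analysis model (NB, exact Hill curves, no batch
  effects, no outliers, independent genes); passing tests demonstrate
  correctness and calibration of the machinery, not robustness to real-data
  pathologies such as correlated genes, sample swaps or isoform switching.
- One TSS per gene; per-transcript TSSs and non-canonical E-box variants are
  out of scope.
- The QL F-test mirrors the standard NB-QL framework's behaviour but is not
  numerically identical to any particular external implementation; the
  deviance small-sample inflation is absorbed by the scale rather than
  corrected per observation.
- Ortholog conversion is an exact two-column lookup; fuzzy identifier
  matching is deliberately not attempted.
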