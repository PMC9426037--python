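# Methods

## Study design the package models

The package operationalizes a two-layer characterization of HER2-low breast
carcinoma (HLBC): a DNA layer (targeted panel of 523 genes over 1.94 Mb,
120 microsatellite loci, gene-level copy number for 59 genes) and an RNA
layer (a ~776-gene breast-cancer expression panel). Samples fall into three
IHC-defined subgroups — score 1+ (HLBC-1), score 2+ FISH-negative (HLBC-2N)
and score 2+ FISH-equivocal (HLBC-2E) — and every statistic is designed to
contrast these subgroups or to discover expression classes orthogonal to
the PAM50 intrinsic subtypes.

## Mutation statistics

**TMB.** TMB = n / panel_mb where n counts somatic variants with
classification in {missense, nonsense, frameshift, inframe_indel, splice}
and VAF strictly greater than 0.05. Both thresholds are strict inequalities.
The non-synonymous set includes indels; panel vendors differ on this point,
so the set is a module constant a caller can inspect. Zero-variant samples
are reported with TMB 0 — dropping them would bias cohort means upward.

**MSI.** Fraction of loci called unstable; the MSI-high flag uses an
inclusive threshold of 0.20 (configurable). No universal panel cutoff
exists; 0.20 is conservative relative to the one clearly MSI-high case
pattern the design anticipates (~40% unstable loci).

**Group tests.** Pairwise mean comparisons use Welch's unequal-variance
t-test: with group sizes as imbalanced as 34 vs 50, pooled-variance t is
anti-conservative when the smaller group has the larger variance. Per-group
95% CIs are mean ± t₀.₉₇₅·SE. Multiplicity is handled with
Benjamini–Hochberg throughout ("FDR adjustment"); the BH implementation is
cross-checked in the tests against an independent step-down computation.

**Signatures.** The 96-context catalog bins SNVs with VAF > 0.1 (strict)
into the canonical pyrimidine-centered trinucleotide classes. Refitting
solves min‖R w − c‖₂ s.t. w ≥ 0 by NNLS on the frequency-normalized catalog
and renormalizes w to mixture proportions. The packaged reference matrix is
synthetic (flat clock-like, CpG-deamination-like, TpC-peaked APOBEC-like
columns plus seeded random profiles) — it exercises the machinery and makes
exact-recovery tests possible, but substantive analyses should pass a
curated reference catalog in the same 96 × S layout.

## Matched-control construction

The control cohort is drawn from a large clinical pool to match the case
series' composition: 90% ER-positive; within ER-positive, 55% grade 3;
within ER-negative, 80% grade 3. Stratum counts come from largest-remainder
rounding (floors plus allocation of remaining units to the largest
fractional parts), so the target total is met exactly and every stratum is
within one sample of its exact share. Sampling is without replacement with
a seeded generator; a single draw is made per specification rather than
resampling. A stratum that cannot supply its share raises an error naming
the stratum and the deficit — silently shrinking the cohort would break the
matching claim.

Differential-mutation testing is two-sided Fisher's exact per gene (the
point-probability method, matching R's `fisher.test`), BH-adjusted across
the tested genes. Genes unmutated in both cohorts have degenerate tables
and are excluded from the BH family; including them would only dilute the
adjustment with exact-1 p-values. The "spider" summary reports the number
of genes below α = 0.05 for raw and adjusted p. Variant-spectrum
comparisons (variant type / classification / pathogenicity) use Pearson's
chi-square without continuity correction, with a Bonferroni factor equal to
the number of cohort pairs compared in the family.

## Expression analysis

**Normalization.** Per-sample scale factor = geometric mean of the
housekeeping-gene counts divided by the cohort mean of those geometric
means; counts are divided by the factor and log2(x+1)-transformed
(pseudocount 1). This is a housekeeping-only approximation to vendor
normalization chains that also use positive controls; values are defined up
to a cohort-level constant, which cancels in every downstream contrast.

**DGE.** Per-gene OLS of log2 expression on a two-level group indicator
plus covariates (categorical covariates are dummy-coded against their first
level). The reported log2 fold change is the group coefficient and its
plain unmoderated t statistic; no variance shrinkage is applied because the
target panels have hundreds (not tens of thousands) of genes and per-gene
residual d.f. are adequate. Rank-deficient designs are refused with the
aliased terms named.

**Pathway and cell-type scores.** The pathway score is PC1 of the
gene-centered member submatrix; PC1's sign is fixed by requiring
nonnegative correlation with the per-sample mean expression of the set,
falling back to "first nonzero loading positive" when that correlation is
exactly zero (e.g. a perfectly anti-correlated pair). Cell-type scores are
mean log2-normalized marker expression.

**GSS / dGSS.** For a gene set S with member t-statistics t_g:
GSS = sqrt(mean t_g²), dGSS = sign(Σ sign(t_g) t_g²)·sqrt(|mean sign(t_g)
t_g²|). |dGSS| ≤ GSS always, with equality exactly when all member t share
a sign; both are permutation-invariant in the set and GSS is monotone in
every |t_g|. These root-mean-square forms follow the gene-set scoring
convention of targeted-panel analysis software.

## Consensus-NMF class discovery

Input is the top floor(0.33 × n_genes) genes by cross-sample variance
(ties broken alphabetically so selection is deterministic). Each restart
factorizes V ≈ WH under the Kullback–Leibler objective with Brunet-style
multiplicative updates and seeded uniform (0,1] initialization, stopping
when the relative KL decrease over a 10-iteration window falls below 1e-6
or at 2000 iterations; updates are monotone, which the tests assert
directly. Defaults: K ∈ {2..6}, 30 restarts; restart seeds derive
deterministically from the master seed via `SeedSequence(seed, spawn_key=(K,
run))`.

Per restart, samples are assigned to their argmax metagene; the consensus
matrix is the co-clustering fraction over restarts. Final labels cut the
average-linkage dendrogram of 1 − consensus at K (standard consensus
practice, more stable than any single run's argmax). The cophenetic
coefficient is the Pearson correlation between the consensus dissimilarities
and the dendrogram's cophenetic distances; a degenerate all-equal distance
vector (perfect one-block consensus) is reported as 1.0.

**Rank selection.** Candidates are ranked by cophenetic coefficient;
candidates whose labels overlap an external subtyping (PAM50) with adjusted
Rand index above 0.6 are discarded first, because the procedure exists to
find classes *beyond* the intrinsic subtypes. The 0.6 threshold is a
configurable design choice — overlap is a continuum and no canonical cutoff
exists. Exact cophenetic ties resolve to the smallest surviving K
(parsimony). An optional `min_k` floor supports designs that require at
least a given number of groups; it is off by default. If every candidate is
discarded the selection raises an explicit "no novel clustering" error
rather than returning a rank.

**Characterization.** Per cluster vs rest: Fisher tests of mutation
prevalence (BH across the cluster × gene family), Welch tests of TMB and
Ki-67, PAM50/grade cross-tabs and mean *ERBB2* copy-number fold change.
Singleton clusters are skipped for the tests with a warning.

## Actionability

Rules are (gene, pattern, OncoKB level, ESCAT tier) records with three
pattern types; match precedence is exact protein change > residue range >
alteration class, verified by tests. A patient is potentially actionable
iff at least one alteration carries any non-none level — the broadest
defensible reading, documented here because tier-restricted definitions
also exist. The packaged rule table is a small synthetic stand-in built in
code (no database export); real analyses should load their own TSV, which
is validated record-by-record at load time. TMB-high defaults to
≥ 10 mut/Mb, the common pan-cancer cutoff, and is configurable.

## Synthetic cohort generator

The generator is the package's study-conditions definition, not a tuning
knob. Defaults: subgroups 34/15/50; prevalences PIK3CA 0.31, GATA3 0.18,
TP53 0.17 (all groups), ERBB2 0.16 within HLBC-2E only (≈8% of the whole
cohort, private to that group); per-group VAF ~ Beta with mean 0.175
(HLBC-1) or 0.25 (HLBC-2N/2E) and concentration 20 — the means are the
targets, the concentration is a realistic spread choice since only interval
summaries constrain it; per-group mean TMB 8.46/4.70/5.18 mut/Mb via
Poisson variant loads; ERBB2 fold-change means 1.3/2.2/4.5 giving the
1 < 2N < 2E gradient; ~1% of samples MSI-high (≈40% unstable loci) against
a 2% background instability.

Expression is V = WH + max(ε, −WH), ε ~ N(0, 0.25²): 300 informative genes
split evenly over K\* = 4 planted metagenes (block loadings ~ U(2,4) against
U(0,0.3) bleed), samples loading U(0.8,1.2) on their planted metagene and
U(0,0.1) elsewhere, housekeeping genes on a high flat baseline and filler
genes on low lognormal baselines. Cluster fractions default to
(12, 28, 15, 30)/85. Because informative-gene variance dominates, the
top-33% selection recovers only informative genes, making the planted rank
identifiable — this is a deliberately low-noise regime. What passing
recovery tests show is that the pipeline's machinery is correct; they do
not show that four classes exist in real HLBC data, where noise is not
Gaussian, clusters are not planted and panel normalization is imperfect.

The control-pool generator emulates a cBioPortal-style breast cohort:
ER+ 75%, G3 50%/75% given ER+/ER−, a HER2 IHC score distribution and
independent per-gene mutation flags at literature-scale rates. Real pools
have gene–gene and gene–covariate correlations the generator omits; the
matching procedure never uses the flags, so this does not affect the
composition results.

## Problem sizes and numerical choices

Simulation-based checks run at the cohort's own scale: 85–99 samples,
256 selected genes, 30 NMF restarts, 10 generator seeds for rank-recovery;
calibration checks use 1,000 binary features over two 200-sample cohorts
and 500 Gaussian genes over 20+20 samples — sizes at which Fisher's
discreteness no longer makes the test conservative beyond a ±0.02 band.
Oracle-equivalence checks enumerate all 2×2 tables with n ≤ 20. NNLS
recovery asserts L∞ < 1e-8 on noiseless catalogs; KL monotonicity is
asserted to 1e-8; consensus-matrix symmetry/diagonal contracts are asserted
on every fit. Numerical guards: multiplicative updates floor denominators
and WH at the smallest positive float; the KL divergence treats 0·log 0
as 0.

## Known limitations

- The housekeeping normalization omits positive-control steps of vendor
  pipelines; absolute normalized values are comparable only within a run.
- Signature refitting is restricted to SBS-style 96-context catalogs; no
  indel or doublet signatures, and no de-novo extraction.
- The DGE model is OLS on log2 values, not a count model; with raw
  NanoString-scale counts and small groups a negative-binomial model would
  be more faithful at the low-expression end.
- Rank selection inherits the instability of ARI on small clusters; with
  very small cohorts the overlap threshold matters and should be reported
  with results.
- The packaged actionability rules are illustrative; clinical use requires
  a curated, versioned rule table.
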