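# hlbc

Analysis toolkit for HER2-low breast carcinoma (HLBC) cohorts profiled with a
targeted DNA panel and a targeted expression panel.

HER2-low tumors — immunohistochemistry score 1+ or 2+ without *ERBB2*
amplification — sit between HER2-negative and HER2-positive disease, and the
question of whether they form one or several biological entities is usually
attacked with exactly the stages this package implements:

- **Panel mutation statistics** (`hlbc.variant_stats`, `hlbc.signatures`):
  tumor mutational burden TMB = #{somatic, non-synonymous variants with
  VAF > 0.05} / panel megabases (1.94 Mb by default); microsatellite
  instability as the fraction of 120 unstable loci; OncoPrint-style per-gene
  frequency tables; pairwise Welch t-tests with BH adjustment; 96-context
  substitution catalogs (VAF > 0.1) refit on reference mutational signatures
  by non-negative least squares.
- **Matched-cohort comparison** (`hlbc.cohort_comparison`): a control cohort
  drawn from a large cBioPortal-style pool to match the case series'
  composition (90% ER+; 55% G3 within ER+; 80% G3 within ER−, via
  largest-remainder stratum counts), then per-gene two-sided Fisher tests
  with BH adjustment, chi-square variant-spectrum comparisons with
  Bonferroni correction, and copy-number gain/loss rate tests.
- **Targeted expression analysis** (`hlbc.expression`): housekeeping
  geometric-mean normalization with log2(x+1); covariate-adjusted per-gene
  OLS differential expression; pathway scores as the first principal
  component of each gene set; and gene-set similarity scores
  GSS(S) = sqrt(mean t_g²) with the signed variant
  dGSS(S) = sign(Σ sign(t_g) t_g²) · sqrt(|mean sign(t_g) t_g²|).
- **Class discovery** (`hlbc.discovery`): consensus non-negative matrix
  factorization (KL multiplicative updates, seeded random restarts) on the
  top-33% most variable genes over K = 2..6; clustering stability measured by
  the cophenetic correlation of the consensus dissimilarities; rank selection
  by best cophenetic after discarding clusterings that merely reproduce the
  PAM50 subtyping (adjusted Rand index above a threshold).
- **Actionability** (`hlbc.actionability`): OncoKB-level / ESCAT-tier
  annotation against a rule table (exact protein change > position range >
  alteration class) with per-patient actionability, TMB-high and MSI-high
  summaries.

Because real HLBC sequencing data are not publicly distributable, the package
ships a first-class synthetic cohort generator (`hlbc.synth`) that emulates
the study design end to end: three IHC subgroups of 34 / 15 / 50 samples,
group-specific mutation prevalences and VAF distributions, TMB contrasts, an
*ERBB2* copy-number gradient, per-locus MSI calls, and an expression matrix
built from K = 4 planted nonnegative metagenes plus truncated Gaussian noise.

## Worked example

```python
from hlbc import (CohortConfig, generate_cohort, generate_control_pool,
                  compute_tmb, group_mean_test, MatchSpec,
                  build_matched_cohort, differential_mutation_test)

cohort = generate_cohort(CohortConfig(seed=7))
tmb = compute_tmb(cohort.variants, samples=cohort.samples["sample_id"].tolist())
groups = cohort.samples.set_index("sample_id")["her2_class"]
print(group_mean_test(tmb.set_index("sample_id")["tmb"], groups).pairs)
```

prints (seed 7):

```
   group_a  group_b    mean_a    mean_b         t             p         p_adj
0   HLBC-1  HLBC-2E  8.596119  5.494845  6.550255  2.857456e-08  4.286184e-08
1   HLBC-1  HLBC-2N  8.596119  4.501718  8.254539  1.073835e-10  3.221506e-10
2  HLBC-2E  HLBC-2N  5.494845  4.501718  2.901722  6.374034e-03  6.374034e-03
```

i.e. the score-1+ subgroup carries a significantly higher mutational burden
(~8.6 mut/Mb) than either score-2+ subgroup (~5.5 and ~4.5 mut/Mb), the
contrast the generator plants and the statistics recover. The same run's
frequency table puts *PIK3CA* at 30/99 (30%) and *GATA3* at 18/99 (18%).

The whole pipeline, including consensus-NMF class discovery and
actionability annotation, runs from the shell:

```bash
hlbc all --outdir run_out --seed 7          # every stage + manifest.json
hlbc synth --outdir cohort_out --seed 7     # just the synthetic tables
```

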