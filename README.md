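# proteostage

Co-expression network analysis and disease staging for cerebrospinal-fluid
(CSF) proteomics.

Tandem-mass-tag (TMT) proteomics can quantify >1500 CSF proteins per
participant, and in Alzheimer's disease these proteins change in waves as
tau pathology spreads through the brain (Braak stages I–VI). `proteostage`
implements the full analysis chain used to resolve that chronology, for
researchers who have a proteins × samples reporter-intensity matrix and
per-participant staging information (amyloid/tau PET, CSF biomarkers, or
cortical biopsy):

- **TMT normalization** — within each TMT set, protein intensities are
  divided by the protein's set-wise median, then each sample by its sample
  median, in log2 space (iterated to a fixed point so sample medians are
  exactly zero); proteins missing in more than 50% of participants are
  excluded.
- **Signed weighted co-expression network** — biweight midcorrelation
  (bicor, maxPOutliers = 0.05) between all protein pairs; signed adjacency
  *a*ᵢⱼ = ((1 + corᵢⱼ)/2)^β at soft power β = 10 (selected for scale-free
  topology R² ≈ 0.9); topological overlap matrix (TOM); average-linkage
  clustering of 1 − TOM with dynamic branch cutting (deepSplit 4, minimum
  module size 10, PAM stage), and merging of modules whose Eigenproteins
  correlate above 0.8.
- **Module summaries** — the Eigenprotein (first principal component of a
  module) as its representative abundance, and kME (protein–Eigenprotein
  Pearson correlation) as module membership.
- **Disease staging** — Aβ PET positivity at SUVR > 1.55, tau PET at
  SUVR > 1.24, hierarchical Braak staging over six regional tau SUVRs with
  discordance detection, CSF Aβ42/40 positivity below 0.061, biopsy-based
  A/T groups, and pooling of sparse stages (e.g. III–IV).
- **Association** — Spearman + Bonferroni module–biomarker tables;
  protein-wise moderated linear models (empirical-Bayes variance shrinkage,
  age/sex covariates, ≥20 observations, BH/Bonferroni); covariate-adjusted
  Tukey HSD group contrasts; joint Aβ + tau PET models; and cross-cohort
  Eigenprotein projection using kME > 0.6 members, z-scored to each
  cohort's controls.
- **Trajectories** — loess (tricube local quadratic) fits of Eigenproteins
  over ordinal stages with 95% confidence bands and inflection flagging.
- **Staging panels** — elastic-net logistic regression (α = 0.7, glmnet
  parametrization, coordinate descent) with stratified cross-validation,
  ROC/AUC, and baseline comparisons on identical folds.
- **Synthetic cohorts** — a generator that plants modules with five stage
  trajectory archetypes (core markers, endolysosomal, immune response,
  metabolic, synapse & membrane), TMT batch structure with pooled reference
  channels, abundance-dependent missingness, and stage-consistent
  PET/CSF/biopsy metadata — ground truth for every stage of the pipeline.

## Worked example

```sh
python examples/02_network_modules.py
```

```text
500 proteins quantified in >50% of 140 samples
5 modules found (gray/unassigned: 296 proteins)
  M1: 62 proteins, variance explained 0.53
  M2: 51 proteins, variance explained 0.50
  ...
adjusted Rand index vs planted modules: 0.976 (1.0 = perfect recovery)
  M1 <-> core_markers: |cor| = 0.948
  M2 <-> synapse_membrane: |cor| = 0.969
  M3 <-> metabolic: |cor| = 0.951
  M4 <-> endolysosomal: |cor| = 0.943
  M5 <-> immune_response: |cor| = 0.959
```

The generator planted five modules among 500 proteins; the network stage
recovers them essentially perfectly (ARI 0.976, background left gray), and
each recovered module's Eigenprotein tracks the latent stage factor that
generated it (|cor| ≈ 0.95). The other examples walk through staging and
association (`03`), stage trajectories (`04`, printing the z-scored
trajectory table with its stage-VI plateaus and drops) and elastic-net
staging panels (`05`).

The same pipeline runs from the shell:

```sh
proteostage simulate --seed 7 --out-dir sim/
proteostage run-all --seed 7 --out-dir run/
```

`run-all` writes normalized matrices, module labels, Eigenproteins/kME,
stage assignments, association tables, trajectories, panel results, and a
provenance JSON with every resolved setting; runs are byte-identical given
the same seed.

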