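# Methods

This note documents the models and procedures implemented in `proteostage`,
the defaults and why they were chosen, the numerical decisions that affect
results, and what the synthetic cohorts do and do not emulate.

## Data model and orientation

Abundance matrices are proteins × samples (proteins are quantified across
participants); all internal math assumes this orientation. Raw reporter
intensities are strictly positive; normalized matrices are log2 ratios and
may contain missing values but never infinities. Every sample belongs to a
TMT set; each set carries one pooled-CSF reference channel used for batch
evaluation and excluded from study-sample statistics.

## TMT normalization

The two-step median-ratio scheme divides each protein's intensities by the
protein's set-wise median (computed over the set's study samples, observed
values only), then each sample column by its sample median, followed by
log2. Two numerical choices:

1. **Log-space sample medians.** The sample-median step subtracts the
   median of the log2 ratios rather than dividing by an interpolated
   intensity median. For odd sample counts the two coincide; for even
   counts only the log-space form makes every sample's median log2 ratio
   *exactly* zero, which is the contract downstream code relies on.
2. **Iteration to a fixed point.** A single pass leaves protein set-medians
   slightly off one (the sample-median step perturbs them), so the whole
   operation is not exactly idempotent. The implementation alternates the
   two median subtractions (a median polish) until the largest adjustment
   falls below 1e-12 — typically a few dozen sweeps. The first sweep is
   exactly the classical two-step procedure; later sweeps apply corrections
   orders of magnitude smaller, and the fixed point makes normalization
   idempotent and its median contracts exact. `max_iter=1` restores the
   single-pass behaviour.

A known, intrinsic property of set-wise median normalization is mild ratio
compression: the set median of 15 study samples contains part of the
biological signal, so subtracting it removes the between-set component of
that signal. On synthetic data this is measurable (see *Recovery
experiments* below); it is a property of the method, not of the
implementation.

Missingness filtering removes proteins missing in **more than** the given
fraction of samples (default 0.5); a protein missing in exactly half is
retained. QC flags samples whose PC1/PC2 coordinates deviate from the
median by more than 4 robust SDs (1.4826·MAD) after median imputation and
centering; flags are advisory and never applied automatically, because
exclusion is a study-level decision. PCA signs are fixed by forcing the
largest-|loading| protein positive, making the report deterministic.

## Network construction

**bicor.** For a vector x: u = (x − med)/(9·MAD), weights (1 − u²)²·1[|u|<1],
with side-capping so at most `max_p_outliers` (default 0.05) of samples per
tail receive zero weight (u is rescaled by the corresponding quantile when
it exceeds 1 in magnitude). A vector with MAD = 0 falls back to Pearson
centering; a constant vector yields correlation 0 with a warning. With
missing data, per-protein medians/MADs/weights are computed once on each
protein's observed values and pair sums run over jointly observed samples
(pairs with fewer than `min_pairs` = 10 joint observations are zeroed with
a warning). This matches the per-pair formula exactly on complete data and
differs only through weight estimates otherwise.

**Soft threshold.** For each candidate power the signed adjacency
((1 + cor)/2)^β is formed, connectivities are binned (~10 equal-width
bins), and log10 frequency is regressed on log10 mean connectivity; the
scale-free fit is the signed-negative-slope R². The chosen power is the
smallest reaching R² ≥ 0.9 with mean connectivity < 100, else the
best-fitting power under the connectivity bound, with a warning. The
pipeline default is a fixed power of 10; automatic selection is opt-in.

**TOM.** TOMᵢⱼ = (Lᵢⱼ + aᵢⱼ)/(min(kᵢ, kⱼ) + 1 − aᵢⱼ) with
Lᵢⱼ = Σ_{u≠i,j} aᵢᵤaᵤⱼ, computed by matrix products; the dissimilarity is
1 − TOM. Since the signed adjacency is already non-negative, the plain TOM
formula is used on it.

**Tree cut.** The branch cut is a documented simplification of the hybrid
dynamic-tree-cut heuristic, contracted to block-model oracles and recovery
invariants rather than label-for-label parity with any other
implementation:

- average-linkage clustering of 1 − TOM;
- a **base cut** at 0.95 of the dendrogram's merge-height range identifies
  coarse branches (TOM dissimilarities concentrate in a narrow high band,
  so cuts are placed relative to the observed height range, not at
  absolute heights);
- each branch with ≥ `min_size` leaves is recursively refined by cutting
  its own subtree at `deep_split`'s fraction of the *local* height range
  ({0: 0.95, 1: 0.9, 2: 0.8, 3: 0.7, 4: 0.6}); a split is kept only when
  it produces at least two children of `min_size` leaves. Higher
  deep_split therefore cuts lower within branches and yields more, smaller
  modules; on nested block structure the module count is non-decreasing in
  deep_split;
- the **PAM stage** assigns each unassigned protein to the module with the
  smallest mean dissimilarity, restricted (when `pam_respects_dendro`) to
  modules inside the protein's dendrogram component at the first merge
  that joins it with any module, and capped at a maximum assignment
  distance (default: the base-cut height). The cap is essential: without
  it every background protein would be absorbed into some module, whereas
  with it proteins far from every module stay gray (label 0);
- a degenerate dendrogram (all merges at one height) yields no modules.

**Merging and summaries.** Modules whose Eigenproteins have dissimilarity
(1 − correlation) below `merge_cut_height` = 0.2 are merged iteratively,
closest pair first, recomputing Eigenproteins after every merge (the
result is invariant to initial label order). Eigenproteins are the first
right singular vectors of the module's standardized submatrix (per-protein
z-scores over observed values, residual missingness imputed with the row
median), sign-aligned to the module's mean standardized abundance; kME is
the Pearson correlation of each protein with each Eigenprotein over
jointly observed samples (≥3 required). An optional post-pass relabels
proteins whose kME to another module exceeds their own with p < 0.05; it
is off by default because its effect is minor.

## Staging

Positivity conventions are strict inequalities — Aβ PET SUVR > 1.55, tau
PET SUVR > 1.24, CSF Aβ42/40 < 0.061 — so values exactly at a cut-off are
negative (ties are practically impossible in measured data; the convention
is documented rather than consequential). Braak staging is hierarchical
over the six regional tau SUVRs ordered I→VI: the stage is the length of
the maximal all-positive prefix; any positive region after the first
negative one makes the pattern *discordant*; all-negative is stage 0.
Global tau status under PET staging is positive iff the Braak stage is ≥ I.
Biopsy cohorts use A+ iff the semiquantitative plaque score is ≥ 1 and T+
iff tangles are present. Clinical strata are diagnosis × Aβ status with CU
and SCI pooled ("CU/SCI_A+", "MCI_A+", ...). Adjacent Braak levels with
fewer than `pool_min_n` = 3 samples are pooled with the next level
("III-IV"), and pooled levels sit at the midpoint of their members on the
ordinal stage axis (CTRL = 0, I = 1, ..., VI = 6). Discordant participants
are excluded from stage trajectories by default (configurable): their
position on the staging axis is undefined rather than intermediate.

## Association statistics

**Spearman tables** rank-transform with average ranks and use the
t-approximation for p-values; the Bonferroni family is all pairs computed
in the invocation, recorded in the output. **Moderated linear models** fit
per-protein OLS (group + age + sex, available cases, ≥ `min_obs` = 20
observations) and shrink residual variances toward a moment-matched
scaled-inverse-chi-square prior: with z = log s² and per-protein residual
df, E[z] and Var[z] have digamma/trigamma closed forms, and d₀ follows by
trigamma inversion (Newton); the posterior variance is
(d₀s₀² + d·s²)/(d₀ + d) and the moderated t has d + d₀ df. Moment matching
was chosen over iterative ML because it is deterministic, closed-form, and
adequate at the ~500–1500-protein scale; `prior_df=0` disables moderation
(reproducing ordinary t exactly), and an infinite d₀ (no excess spread in
the observed variances) pins all variances at the prior. **Tukey HSD**
fits one linear model with group dummies and covariates and tests all
pairwise covariate-adjusted differences against the studentized-range
distribution (scipy's quadrature; its k = 2 case agrees with the pooled
t-test to ~1e-9, well inside the documented 1e-6 contract); unadjusted
t-test p-values are reported alongside. **Dual-PET models** put both SUVRs
in one per-protein model with age, sex and diagnosis, warn at |r| > 0.99
between predictors, and BH-adjust each predictor's p-values across
proteins. No imputation is used in inference; models drop missing
abundances case-wise.

**Cross-cohort projection** takes a module's discovery members with
kME > 0.6 that are present in the target cohort (≥3 required; coverage is
reported), standardizes them in the target, and extracts the first
principal component across target samples (a mean-z variant is available;
the two correlate >0.95 in practice). The sign is aligned so the
kME-sign-weighted mean correlation with the members is positive, and
values are z-scored to the target cohort's own controls (mean 0, SD 1 by
construction, SD with n−1).

## Trajectories

Loess fits use tricube weights and local degree-2 polynomials over the
ordinal stage axis, evaluated at the observed stage positions only (no
extrapolation). Two numerical adaptations for heavily tied ordinal
positions: the k-nearest window is grown until it contains at least
degree + 2 distinct positions (the farthest position always carries zero
tricube weight, so this keeps the local quadratic well-posed at boundary
stages), and spans above 1 inflate the bandwidth so span → ∞ reproduces
the global polynomial fit. Pointwise 95% bands come from the
linear-smoother variance with residual df = n − tr(L). Span 0.75 and
degree 2 are display defaults, recorded in every fit. The trajectory
summary z-scores each fitted series over the grid, applies recorded
vertical offsets for comparability, and flags stages where the fitted
derivative changes sign as candidate inflection points.

## Staging panels

Elastic-net logistic regression in the glmnet parametrization
(objective (1/n)·deviance/2-form + λ(α‖β‖₁ + (1−α)/2‖β‖₂²), α = 0.7 by
default), solved by cyclic coordinate descent on the IRLS working response
with warm starts along a log-spaced λ path (50 values from the
null-model λ_max down to 0.01·λ_max when n < p, 1e-4 otherwise) and an
active-set strategy with full-sweep verification. Features are
standardized internally; coefficients are reported on the original scale.
Stationarity (KKT) residuals at the solution are checked to ~1e-13 in
tests, and the solver agrees with an independent implementation at matched
penalties to ~3e-10. λ is chosen by minimum mean CV binomial deviance over
stratified folds (one-SE rule available); the reported CV-AUC is computed
from out-of-fold decision scores at the chosen λ, and fold assignments are
exported so baseline models can be compared on identical splits. Missing
abundances are median-imputed before fitting (the pipeline imputes on the
full contrast cohort; no leakage-sensitive statistics are computed from
the imputed values beyond the panel itself). AUC uses the midrank
Mann–Whitney identity, which handles ties exactly.

## Synthetic cohorts: what they emulate, and what they do not

The generator plants a latent-factor model chosen to mirror how the
analysis summarizes data (Eigenprotein ≙ latent factor, so fidelity is
directly measurable): for a module protein,

log2 value = baseline + loading × (template[stage] + jitter) + batch + noise,

with loadings U(0.4, 0.95), baselines N(10, 1.5²), per-TMT-set per-protein
batch offsets N(0, 0.3²), per-sample module-specific jitter N(0, 0.8²),
and measurement noise N(0, 0.5²) at the defaults. Five archetype templates
(values fixed in code; the source trends are qualitative, so shapes — not
magnitudes — are the contract): core markers rise stepwise through stage V
and plateau at VI; endolysosomal peaks by stage II and returns toward
baseline; immune response dips in early/mid stages and recovers by VI;
metabolic rises near-linearly through V and drops sharply at VI; synapse &
membrane stays flat through V and drops at VI. The jitter term is the
biological between-subject variation that makes modules statistically
separable from one another despite sharing the stage axis; at 0.8 it
dominates the template range, which is the realistic regime (stage
explains a minority of between-person variance).

Metadata are generated consistently with the latent stage: regional tau
SUVRs follow the hierarchical prefix rule with a 10% discordant flip
(exercising the discordance branch); Aβ PET positivity probability rises
from 0.15 (CTRL) to 1 (stage IV+); CSF p-tau/t-tau are monotone in stage
with a stage-VI plateau and the Aβ42/40 ratio declines early; diagnosis is
a deliberately noisy function of stage (CU/SCI/MCI/AD mixtures per stage);
ages are stage-correlated (55–85), sexes balanced. Missingness is
protein-level Bernoulli with probability decreasing in baseline abundance
(left-censoring-like) and mean `missing_rate` = 0.1. Validation cohorts
reuse the discovery loadings and templates on a configurable fraction of
the protein universe (default 0.7), with fluid (CSF-ratio + diagnosis) or
biopsy (plaque score + tangle flag) staging drawn consistently with stage.

What the generator does **not** emulate — and hence what passing recovery
tests do not demonstrate about real data: peptide/spectrum-level effects
(isotope impurity, co-isolation interference, peptide-to-protein rollup),
non-Gaussian abundance distributions, correlated missingness across
proteins, module overlap (each protein belongs to at most one module),
longitudinal structure, and realistic identifier semantics. The synthetic
CSF core biomarkers are idealized monotone functions of stage; they are
*more* informative relative to the proteome than real immunoassay
measurements, so baseline comparisons on synthetic data can favour the
core-biomarker baseline even where panels win on real data.

## Recovery experiments (what the test suite measures)

At the default conditions (5 modules of 60/50/40/30/20 proteins, 300
background, 20 samples per stage across CTRL + Braak I–VI, noise sd 0.5),
the network stage recovers the planted partition with ARI 0.97–0.99 over
seeds 1–5, with background left gray. Eigenprotein–latent-factor fidelity
is ≥0.9 for 24 of 25 module × seed combinations; the exception is the
smallest, weakest-template module on one seed (0.866), attributable to the
ratio compression of set-wise median normalization described above
(un-normalized data give 0.97 for the same module). Self-projection
fidelity exceeds 0.99 and projection into a 70%-overlap validation cohort
tracks the latent factor at ≥0.95. The early (I–II) vs mid (III–IV) stage
panel attains out-of-fold CV-AUC ≈ 0.47–0.90 depending on the seed
(population d′ ≈ 1.25 at the default jitter puts the attainable AUC near
0.8, so the estimate straddles it at n ≈ 70); this spread brackets the
0.69–0.86 band typical of such panels on real cohorts. These are
properties of the stated study conditions, not tuning targets.

Problem sizes in the tests and acceptance script (500-protein cohorts,
140 study samples, 3–5 seeds per experiment) were chosen as the smallest
sizes at which the recovery statistics are stable; the full suite runs in
well under a minute.

## Known limitations

- The tree cut is a simplification of the hybrid dynamic algorithm; on
  dendrograms with gradual, non-nested structure it may split or lump
  differently than the full heuristic.
- bicor with missing data estimates weights per protein, not per pair.
- The moderated model assumes a single variance prior across proteins (no
  abundance-dependent trend) and no robustification against variance
  outliers.
- Panels impute missing abundances with cohort medians before CV rather
  than within training folds; at the 10% missingness default the effect is
  negligible, but for heavily missing data fold-internal imputation would
  be preferable.
- Stage positions are ordinal-equidistant; no attempt is made to model
  unequal biological spacing between Braak stages.
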