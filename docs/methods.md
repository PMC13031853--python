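# Methods

`tractage` implements a tract-specific white-matter brain-age analysis:
normative Gaussian-process (GP) age models fit to along-tract fractional
anisotropy (FA) profiles, bias-corrected brain-age gaps (BAGs), sparse
canonical correlation analysis (sCCA) linking BAGs to behavior,
group-level clinical models, and tract-wise spatial decoding against
volumetric maps. Because the cohorts this kind of analysis targets are
access-restricted, the package ships a synthetic cohort generator whose
statistical structure matches every assumption the downstream stages
make, so the whole chain is testable end to end.

## Synthetic cohort generator

Each of 54 tracts (25 bilateral pairs across six tract systems plus four
callosal tracts) carries a 100-node FA profile. Node-level FA follows a
logistic maturation curve

    FA(age) = f0 + (f1 - f0) / (1 + exp(-k (age - t0)))

with floors f0 ~ U(0.22, 0.32), ceilings f1 = f0 + U(0.12, 0.22), rates
k ~ U(0.25, 0.6) /year and midpoints t0 ~ U(9, 14) years, varied
smoothly along nodes (mid-tract FA above endpoint FA). These ranges give
developmental trajectories with most maturation between late childhood
and late adolescence, the regime the normative models are meant to
capture.

**Planted deviations.** Each subject deviates from the normative
trajectory by a tract-system-level offset in years (SD
`deviation_sd = 2.0`), shared across the tracts of a system plus small
tract-level jitter (SD 0.25 y). The tract profile is evaluated at
`age + deviation`, so the deviation *is* the ground-truth BAG. Systems
belonging to one of the two latent modes share a mode-level factor
(`mode_share = 0.5` of the deviation variance); this makes the planted
brain-behavior modes load on whole tract systems, which is what the
sCCA stage is designed to find.

**Modes and behavior.** Two planted modes couple deviations to behavior
blocks: an association mode (dorsal + ventral association systems →
20 cognitive scores) and a subcortical/limbic mode (the remaining five
systems → 31 psychopathology scores). Each loaded behavior column is
`r·latent + sqrt(1-r²)·(block-shared noise) + 0.3·(unique noise)` with
coupling `r = 0.3`, where the latent score is the standardized mean
deviation over the mode's systems. The block-shared noise term keeps the
correlation between the latent score and the block composite at ≈ r.

**Site effects and noise.** Per-site, per-feature additive shifts
(SD 0.02 FA) and multiplicative residual scale factors (log-SD 0.25)
emulate scanner differences in the form ComBat models. Measurement noise
has a node-level i.i.d. part (SD 0.04 FA) and a tract-level part shared
along the tract (SD 0.02 FA): noise along real tract profiles is
spatially correlated, and without the correlated component node
averaging would make profile noise irrelevant to BAG accuracy. FA is
clipped to [0, 1] after noise; the clip count is recorded in
`profiles.attrs["n_clipped"]`.

**Diagnoses.** A standard-normal liability `-w·(association deviation) +
noise` (w = 0.5) is thresholded into 0 / 1 / ≥2 diagnosis-count classes
with baseline marginals (0.752, 0.156, 0.092) and follow-up marginals
(0.795, 0.141, 0.064), the class proportions of a large developmental
sample. Follow-up liability correlates 0.6 with baseline, producing all
four healthy/diagnosed transition cells (HH/PH/HP/PP) at realistic sizes.
The negative weight encodes the direction of interest: delayed
maturation (negative BAG) raises diagnosis liability.

**Puberty and hormones.** PDS item scores (3 male items summing 3-12;
2 female items summing 2-8, plus a menarche flag) increase stochastically
with age and with the association-system deviation. Salivary hormones are
log-normal in age, truncated to the quality-control plausibility ranges
(DHEA 5-1000, testosterone 5-500, estradiol 0-1500 pg/ml). Collection
covariates (caffeine, physical activity, collection time/duration,
freeze time) are generated for the mixed-model analyses.

**What the generator does not emulate.** Real dMRI artifacts (motion,
distortion), tractography failures and partial-volume effects; age- or
site-dependent missingness; non-Gaussian behavior distributions; more
than two visits. Passing tests therefore show that the estimators
recover the structure they model, not that the model is adequate for any
particular real cohort.

## Harmonization (ComBat)

Standard parametric empirical-Bayes ComBat: features are standardized by
a covariate-adjusted grand mean and pooled variance; per-site location
(γ) and scale (δ²) estimates are shrunk toward normal and inverse-gamma
priors with method-of-moments hyperparameters, iterating the conditional
posterior means to a relative tolerance of 1e-4 (max 100 iterations).
Biological covariates to preserve (age, sex, and the diagnosis-count
class as two dummy columns) enter the standardization design. Single-site
input is an identity transform; a site with one subject is an error
(scale undefined). The implementation matches Bioconductor's
`sva::ComBat` to ~1e-15 on shared inputs (cross-checked in the test
suite via `Rscript`). `eb=False` disables shrinkage for exact checks on
planted effects.

## Brain-age models and BAGs

Feature assemblies concatenate bilateral pairs (left nodes 1-100 then
right, p = 200), use single callosal profiles (p = 100), or concatenate
all 54 tracts (p = 5400, "whole-brain"). The regressor is an exact GP
with kernel `σ_f²·RBF(ℓ) + σ_n²·I` on z-scored features (training
statistics only), hyperparameters by marginal-likelihood maximization
with seeded restarts. Predictions are posterior means; a direct
`k*ᵀ(K+σ²I)⁻¹y` computation is kept as an independent oracle.

Accuracy (Pearson R, RMSE) is computed on concatenated out-of-fold
predictions from seeded, age-decile-stratified k-fold CV (default k=5; a
separate 20% hold-out path is available), always from *uncorrected*
predictions. Significance uses an age-permutation test with
p = (count + 1)/(n_perm + 1), BH-FDR across models applied by the
caller.

BAG = predicted − chronological age. Because regression toward the mean
makes raw BAGs anticorrelate with age, a line BAG = α·age + β is fit in
the training subjects and subtracted everywhere. In
`crossval_bag_table`, the GP, the standardization and (α, β) are
re-estimated inside each training fold, so every subject's corrected BAG
is fully out-of-sample.

## Sparse CCA (penalized matrix decomposition)

The rank-1 subproblem maximizes uᵀ(XᵀY)v subject to ‖u‖₂ = ‖v‖₂ = 1 and
L1 budgets C₁√p, C₂√q (C ∈ (0,1]; a budget below 1 is infeasible under
the L2 constraint and is clamped to 1). Updates alternate
u ← project(Zv), v ← project(Zᵀu), where the projection soft-thresholds
to meet the budget; the threshold is found in closed form on the sorted
magnitudes (the constraint is quadratic in the threshold for each
support size). Convergence: max iterate change < 1e-6, with a secondary
stop when the objective is stationary (sparse near-ties can cycle
between solutions of equal objective; the final iterate is returned with
a warning). Successive modes deflate Z ← Z − d·uvᵀ. With C₁ = C₂ = 1 the
modes equal the SVD singular pairs of XᵀY (tested to 1e-6).

Inputs are residualized on age and sex (full-sample OLS, then z-scored).
Sparsity is selected on a 0.1-1.0 × 0.1-1.0 grid (100 combinations; 0
forces a zero vector and is excluded) by the mean first-mode canonical
correlation over ten random two-thirds subsamples. Mode significance:
rows of Y permuted, model refit, p = (count R_perm ≥ R_obs + 1)/(n+1),
BH-FDR across modes. Loading inference: bootstrap over subjects; each
bootstrap mode is aligned to the reference mode by maximal |correlation|
of variate scores (sign-flipped if negative) and percentile 95% CIs are
formed on structure loadings (variable-variate correlations; raw sparse
weights are also emitted — the two are reported side by side since
published analyses are ambiguous about which is plotted). Mode
specificity: paired Cohen's d (mean/SD of bootstrap differences of
absolute loadings) ≥ 0.5 favoring one mode over every other. Sign
convention: each mode is oriented so the summed loadings of the
designated block (cognition by default) are positive.

## Group-level models

- **BAG ~ behavior GLMs** controlling age and sex; t test on the
  behavior coefficient; BH-FDR over the full tested family.
- **Group factors** (diagnosis-count classes, transition classes):
  omnibus partial F comparing models with/without the factor dummies;
  post-hocs by Tukey-Kramer on covariate-adjusted means using the
  studentized-range distribution (raw means available via
  `adjusted=False`).
- **GAM incremental variance**: outcome modeled on a cubic B-spline
  basis in age (dimension 10) plus sex, with and without the BAG term;
  effect size is 100·(adjR²_full − adjR²_null) with a partial-F p-value.
  Regression splines of fixed dimension were chosen over penalized
  smoothing because no REML-smoothed GAM is available in the stack and
  the incremental-R² contract is insensitive to that choice at these
  basis dimensions.
- **Developmental LMMs**: random-intercept models (REML) of BAG on
  pubertal stage (Eq.-3-type) or hormone level with collection
  covariates (Eq.-4-type), two visits per subject. The t test for the
  predictor uses a residual-type df approximation
  (n_obs − n_fixed − n_subjects + 1); singular random-effect fits are
  flagged, not dropped.
- **PDS staging**: deterministic sex-specific rules — males (sum of 3
  items): 3 prepubertal, 4-5 early, 6-8 mid, 9-11 late, 12 postpubertal;
  females (sum of 2 items): 2 prepubertal, 3 without menarche early, >3
  without menarche mid, ≤7 with menarche late, 8 with menarche
  postpubertal.
- **Effect-pattern similarity**: Spearman correlation of tract-wise
  effect vectors with average-rank ties; exact permutation p for ≤10
  tracts, t approximation otherwise.
- **BH-FDR**: standard step-up adjustment (statsmodels backend, verified
  against a hand-computed oracle).

## Spatial decoding

Tract-wise profiles of a volumetric map are means over voxels with tract
probability ≥ 0.5 (optionally intersected with a grey-matter mask),
z-scored across tracts. Affines and grids must match bit-exactly; there
is no silent resampling. Respiratory-capacity maps follow
TRC = (√CI + √CII + √CIV)/3 and MRC = TRC/MitoD (MRC flagged NaN where
density is zero). Profiles are compared to sCCA loading patterns by
Spearman correlation.

Significance uses spatial-autocorrelation-preserving surrogates built by
variogram matching on tract centroid distances: each surrogate permutes
the profile, smooths it with a Gaussian kernel over the distance matrix
(bandwidths at fixed fractions of the maximum distance), and regresses
the surrogate variogram onto the empirical one to set the smooth/white
mixture; the bandwidth with the lowest variogram SSE is kept. Tract
volumes have no spherical parameterization, so this one engine replaces
both rotation-based tools used for surface data, with default iteration
counts 1000 (topic decoding) and 10000 (mitochondrial) preserved as
configuration. With fewer than 10 tracts a plain permutation null is
used with a warning. One-sided p = (count ≥ observed + 1)/(n + 1),
BH-FDR across the map family. Under spatially uncorrelated profiles the
surrogate null is calibrated (Spearman ranks of i.i.d. draws are uniform
permutations, so the two nulls coincide); under autocorrelation it is
wider than the plain permutation null, which is the point of the method.

Network overlap: pooled thresholded voxels of a mode's tracts are
intersected with a 7-label cortical-network parcellation; proportions
are over labeled voxels and sum to 1.

## Pipeline

`tractage run config.yaml` executes simulate → harmonize → brain-age →
sCCA → group models → decode, each stage reading and writing only
serialized artifacts (TSV/JSON/YAML) in the output directory. Every
stochastic stage derives its seed from the config seed; the JSON
manifest records a config hash (excluding output paths), SHA-256
checksums of all outputs, and wall times. Re-running an identical config
reproduces identical checksums; `resume: true` skips stages whose
outputs exist. The default configuration runs 500 subjects, one
representative bilateral pair per tract system plus the whole-brain
model (scaled so a full run takes minutes on one CPU); the tract list,
fold count, permutation/bootstrap counts and surrogate counts are all
configuration. The decoding stage demonstrates the map machinery on a
synthetic box-tract atlas and synthetic enzyme maps (the `demo_atlas`
helper), since real atlases are large binary inputs.

## Numerical choices and degenerate inputs

- GP noise variance is bounded below (1e-5 by default) to keep the solve
  well-conditioned; noiseless fixtures push it to the bound, which is
  the intended optimum there.
- ComBat rejects singular designs, sites with one subject, unseen site
  labels at transform time, and constant features (zero pooled
  variance).
- Residualization rejects columns that become constant (e.g. a column
  exactly linear in a covariate).
- Tract-profile z-scores are defined as 0 when the across-tract SD is
  (numerically) zero.
- Tie-breaks: the sparsity grid search prefers the sparser (smaller)
  constants on ties; PMD orients d ≥ 0; mode signs follow the
  sign-block convention.
- All Monte-Carlo machinery takes explicit integer seeds and is
  bit-reproducible; tests and the acceptance script run at reduced but
  stated problem sizes (e.g. n = 600 for deviation recovery, 200
  calibration replicates at 200 permutations) chosen to exercise each
  property with clear margins.

## Known limitations

- Out-of-sample application of a fitted brain-age model to a *new
  cohort* (the external-validation scenario) is supported by the
  estimator API but the shipped pipeline evaluates by cross-validation
  within one cohort.
- Non-parametric and longitudinal ComBat variants are out of scope.
- The LMM df approximation is cruder than Satterthwaite for small or
  very unbalanced designs.
- The variogram surrogate engine works on tract centroids, a coarse
  summary of tract geometry; very elongated tracts with similar
  centroids are treated as spatially close.
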