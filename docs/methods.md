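# Methods

## Study design the package models

The pipeline targets paired-design plasma lipidomics: each subject is sampled
before a chemotherapy course (day 1) and, when available, after it (day 2);
day-2 subjects additionally carry a binary neuropathy outcome. Two binary
tasks follow: *timepoint* (all samples, day 1 vs day 2) and *neuropathy*
(day-2 samples only). Because the two samples of a subject are strongly
correlated, every data split in the package — holdout segregation, CV folds,
per-run training subsamples — operates on subjects, never on samples.
Neuropathy is stored as `unknown` on day-1 rows by construction; a day-1 row
can only be associated with an eventual outcome through an explicit subject
join, so the label can never leak into a day-1 feature vector.

## Synthetic cohort generator

The generator is the package's test bed and benchmark: it emits cohorts with
the exact shape of the motivating design (default: 48 day-1 + 31 day-2
samples × 255 lipid mediators; 17/31 day-2 subjects neuropathy-positive;
optionally a 52 × 239 all-paired external cohort) and a declared ground truth
of informative features.

Log-scale model per cell:

    log x_ij = base_j + subject_i,j + block + class shifts + noise

- `base_j ~ U(0, 4)` sets per-feature abundance spread over ~2 decades,
  a typical dynamic range for quantified lipid panels.
- `subject_i,j ~ N(0, 0.5²)` is a per-subject random effect shared between a
  subject's day-1 and day-2 samples (independent across features). It creates
  the within-subject correlation that makes sample-wise splitting leak.
- The residual combines a block factor shared by features of the same block
  (10 blocks, within-block correlation 0.4, mimicking co-regulated lipid
  classes) with white noise, total SD 0.5.
- Class shifts are expressed in units of the within-class log SD
  √(0.5² + 0.5²) ≈ 0.71. Defaults: 10 time-informative features at effect
  1.5, 3 neuropathy-informative at 1.0, signs alternating at random (lipids
  move in both directions). 60% of the time-informative features are drawn
  from the first annotated class ("sphingolipid", 46/255 of the panel), so
  class over-representation among top hits is a recoverable property.
- Missingness is MCAR at rate 0.05 after exponentiation. MCAR is the neutral
  choice when the true mechanism is unknown and keeps the imputation
  benchmark unbiased.

What the generator does **not** emulate: batch drift, limit-of-detection
censoring (missingness in real MS data is abundance-dependent), heavy-tailed
measurement error, or correlated outcomes. Tests passing on this generator
show the *algorithms* behave as specified under a known truth, not that real
cohorts carry recoverable signal.

A note on calibration: the within-block correlation parameter is defined on
the residual; the subject effect (independent across features) adds variance
but no covariance between features, so empirical feature–feature correlation
equals `block_rho` only when `subject_sd = 0`. The calibration check in the
test suite uses that setting.

The external-cohort generator reuses the primary cohort's informative
features and signs, drops 16 uninformative features (panel shrinkage between
sites), and multiplies effect sizes by an attenuation factor in (0, 1]
(default 0.5) to emulate the weaker signal of an externally collected cohort.

## Preprocessing

- **Transformation choice.** Tukey's ladder {−2, −1, −½, 0, ½, 1, 2} is
  scanned; each rung is scored by the number of features passing a
  D'Agostino–Pearson omnibus normality test (K² = Z(skew)² + Z(kurt)²,
  χ²(2) p-value; requires ≥ 20 observations) at p > 0.05; ties go to the rung
  closest to 1. Log-normal concentrations select the log (λ = 0).
- **Missingness filter.** Features, then samples, with a missing fraction
  strictly above 0.2 are dropped. Boundary cases exactly at 20% are retained
  (the conservative reading). Features go first so a handful of badly
  measured analytes cannot disqualify patients; the sample pass then uses
  missingness over the retained features only. The filter is idempotent.
- **Imputation.** Iterative random-forest (missForest-style): initialize with
  feature medians, sweep features in order of increasing missingness, regress
  each on all others with a 100-tree forest (mtry = √p, the standard
  forest-imputation default) and overwrite its missing cells. Sweeps stop at
  relative change < 1e-3, on divergence (change increasing, keeping the
  previous state), or after 10 sweeps. Observed cells are never altered;
  the result is deterministic given the seed. The whole matrix is imputed
  once, before holdout segregation, matching the workflow order this pipeline
  reproduces; the functions can equally be applied per partition.
- **Standardization.** Per-feature z-score with mean/SD estimated on an
  explicit fitting partition. Inside validation the fitting partition is
  always the training side — fitting on all data would leak holdout location
  and scale.

## Computed ABC analysis

Items sorted descending (stable, so ties keep input order; a warning is
emitted when tied values straddle a boundary); curve points
(xᵢ = i/n, yᵢ = cumyield). The A|B limit minimizes the Euclidean distance to
the ideal point (0, 1). The B|C limit is break-even: on the uniform x-grid
the slope of segment i equals valueᵢ/mean, so B ends with the last item at or
above the mean; if break-even precedes A|B, B is empty. An all-equal vector
(n > 1) is degenerate: no concentration signal, everything is C. Nested cABC
re-applies the procedure to category A until the requested depth or until A
stops shrinking; demoted items keep the category of the stage that removed
them. |A| ≥ 1 for non-degenerate input, categories are scale-invariant, and
deeper nesting never grows A — all property-tested against an exhaustive
boundary-search oracle.

## PCA structure and ESOM/U-matrix

PCA eigen-decomposes the feature correlation matrix (trace = d). Components
with eigenvalue strictly > 1 are retained (Kaiser); feature importance is the
squared loading on each retained component weighted by the component's
explained-variance fraction, summed; cABC category A of that vector is the
"important few".

The ESOM uses a 50 × 80 toroidal grid (configurable; tests use smaller grids
for speed), weights initialized by sampling data rows with replacement,
online updates over 20 epochs with per-epoch reshuffling, Gaussian
neighborhood on toroidal grid distance, learning rate and radius decaying
linearly over all updates from (0.5, max(rows, cols)/2) to (0.01, 1). The
decay schedule and neighborhood form are conventional choices and are
config-exposed. U-height of a neuron is the mean weight-space distance to its
8 toroidal neighbors (8-neighborhood matches the visual U-matrix
convention). Cluster extraction thresholds the height field: scanning
quantiles from high to low, the first threshold whose sub-threshold neurons
form at least the requested number of BMU-bearing 8-connected components is
taken — the threshold just under the separating ridge, a programmatic stand-in
for the visual watershed reading. Ridge-top BMUs join the nearest component
by toroidal grid distance. A flat field raises a clustering failure rather
than inventing clusters.

## Consensus feature selection

The 13-member ensemble: PCA importance, |Cohen's d| (pooled-SD form;
zero-spread features score 0), F-test FPR (p < 0.05), FWE (p < 0.05/d),
k-best, and {k-best, SelectFromModel, RFE} × {linear SVM, random forest,
logistic regression}. Selection-stage models are light on purpose (linear
SVM via LinearSVC, 100-tree forests): they only rank features, and the
coefficient-based selectors require linear models. SFM thresholds importance
at its mean (|coefficients| for linear models, impurity importance for
forests). RFE eliminates 10% of the feature count per round (floored to one
feature, so small panels eliminate one at a time); the panel size k for
k-best/RFE is tuned once per task over k ∈ 1..18 by 5-fold inner-CV balanced
accuracy of the paired model and then held fixed across folds. A selector
that fails on a fold contributes nothing for that fold and the failure is
logged.

Folds are `StratifiedGroupKFold(5)` repeated 20 times with distinct seeds —
100 training folds, subjects never split. Counts are accumulated per method;
cABC of each method's count vector gives its A-set (scale invariance makes
counts and frequencies equivalent); the sum score counts, per feature, the
methods whose A-set contains it (0..13); cABC of the sum score yields the
reduced panel and nested cABC (depth 2) the sparse panel.

## Validation

Holdout segregation samples 20% of subjects per stratum (a subject's stratum
is the set of class labels its samples carry, so paired subjects stay whole).
Tuning is a 5-fold grid search per family (SVM kernel ∈ {linear, sigmoid};
forest 200/600/1200 trees × depth 5/10/∞; logistic-regression C), with the
known-good configurations pre-seeded as defaults (sigmoid SVM; 1200×10
forests for the timepoint task, 200 trees for the smaller neuropathy task;
newton-cg ridge logistic regression). The linear/L1 form of the SVM lives in
the selection stage, where coefficients are needed; the kernelized sigmoid
form in validation — an L1 coefficient penalty is undefined for a kernel
machine, so the two roles use the two forms.

Each of the 100 validation runs draws a class-proportional subject-grouped
80% subsample of the training partition (permuting its labels when the
control is requested), fits each family on the panel's columns, and scores a
sample-wise random 80% subsample of the holdout. Balanced accuracy is the
mean of per-class recalls; ROC-AUC is the Mann–Whitney form (ties ½) on the
decision margin (SVM, logistic regression) or positive-class vote fraction
(forest). Summaries are the median and raw 2.5th/97.5th percentiles over
runs; a panel "separates from chance" when that interval excludes 0.5.
Degenerate draws (a subsample with one class) are skipped rather than
scored. Label permutation is applied within the training subset: it severs
the feature–label link while preserving feature marginals, which is the
standard overfitting control. External cohorts are scored by the frozen
models fit once on the full training partition, with CIs from repeated 80%
subsampling of the external cohort; the external cohort is standardized with
its own statistics, as a second site would be.

## Pipeline

`run_pipeline` derives every stage seed from one master seed via SHA-256, so
reruns are bit-identical. For the neuropathy task the pipeline formalizes the
design rule that multivariate selection requires a working classifier: when
every family's balanced-accuracy CI on the reduced panel contains 0.5, the
stage is re-run with univariate selectors only (Cohen's d, FPR, FWE). The
complementary hypothesis-transfer route — validating the timepoint task's top
panel directly on the neuropathy labeling — is a one-line `validate` call
with that panel and is left to the analyst rather than auto-chained. By
default the whole matrix is imputed once before segregation;
`PipelineConfig.impute_per_partition = True` switches to imputing train and
holdout independently for the strictest leakage control. Stage
artifacts (tally CSV, panel JSON, per-marker Kruskal–Wallis table with BH or
Holm adjustment, summary JSON stamped with the config hash) are written even
when later stages fail.

## Problem sizes and numerical notes

Default study-scale runs (79 × 255 cohort) complete in minutes on one core:
the imputer is the costliest preprocessing step (≈ 250 forest fits per
sweep, 2–3 sweeps typical), the consensus stage fits ≈ 1 300 selector rounds,
and each validation block fits 300 classifiers. Tests and examples use
smaller cohorts and grids where full scale adds nothing to the property under
test; the acceptance script runs the full default shape. Ties are broken
deterministically throughout (stable sorts; smallest index for equidistant
BMUs and tied F statistics). Fisher's exact test uses the conditional-MLE
odds ratio with the exact conditional CI — the convention under which
published odds-ratio/CI values from standard statistical environments are
comparable. The Kruskal–Wallis H for a pooled sample of identical values is
reported as H = 0, p = 1 (no evidence of difference) rather than NaN.

## Known limitations

- The U-matrix cluster reading is a thresholded-components approximation of
  the visual watershed; maps with more than two genuine clusters are reported
  as "≥ n_clusters found", not segmented optimally.
- The neuropathy task at its study-sized default (31 day-2 samples) sits at
  the edge of what subject-grouped 5-fold CV supports; expect wide CIs.
- The iterative imputer assumes MCAR-ish missingness; under
  abundance-dependent censoring it will bias low concentrations upward.
- Grids for hyperparameter tuning are intentionally small; the package
  validates panels, it does not chase classifier leaderboards.
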