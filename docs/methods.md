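# Methods

This note records the modelling choices behind `csfpanel`: what is
simulated, how the two selection engines are defined, the numerical
conventions, and what the synthetic experiments do and do not establish.

## Study design being emulated

The package targets the analysis design of multi-centre genetic-FTD CSF
studies: a cohort of affected mutation carriers (AMC), presymptomatic
carriers (PMC) and non-carriers (NC); a multiplexed antibody bead-array
readout of ~111 proteins in arbitrary units; and two comparisons —
affected (restricted to bvFTD/PPA phenotypes) versus everyone
unaffected, and PMC with expected TDP-43 pathology close to onset
(C9orf72 carriers older than 48, GRN carriers older than 51; MAPT and
TBK1 excluded) versus NC older than 48. Years to expected onset are
computed as the gene-level mean onset age minus current age; the default
gene means (C9orf72 58, GRN 61, MAPT 49) place the "older than" cut-offs
about ten years before expected onset.

## Synthetic-data generator

`generate_cohort` draws a 221-sample cohort (47/98/76) with the gene
split (27/12/7/1 in AMC, 41/38/16/3 in PMC), phenotype split (32 bvFTD,
7 PPA, 8 other) and per-group sex ratios of that design. Ages are
truncated normals (AMC 62±9 on [38,76], PMC 46±12 on [20,74], NC 47±13
on [20,69]); because truncation shifts the realized mean, the parent
location is calibrated numerically so the *truncated* mean equals the
configured group mean — generated cohorts therefore match the target
demographic table, not just its parameters.

`generate_assay` builds log-intensities as

    log S_ij = b_j + s_j (Z_ij + delta_ij) + plate_{p(i),j}
               + drift * q_i + eps_ij

with per-protein baselines `b_j` (a fixed deterministic spread over
5.5–8.5 log-AU), latent SD `s_j = 0.3`, standard-normal latents `Z` with
single-factor equicorrelated blocks, planted shifts `delta` in latent-SD
units applied to contrast-defined samples, per plate-by-protein
offsets (SD 0.1), a linear log-scale drift over the readout-order
quantile `q_i` (default 0.3 log-units end to end — a visible but
realistic within-batch trend), and log-noise of SD 0.1. Signals are the
exponentials, hence strictly positive. Plate assignment mimics
constrained randomization (stratified by group, sex and age tertile);
one RNG stream drives each dataset and the seed is stored in the truth
table.

Default planted effects (latent-SD units): NEFM +2.1, AQP4 +1.8,
NPTX2 −1.9, VGF −1.8 in affected samples, and GRN −2.0 in GRN mutation
carriers (haploinsufficiency). Two calibration considerations fixed
these defaults before the acceptance experiments were frozen:

* the strongest marker alone should give a single-model ROC AUC near
  0.9, the level reported for neurofilament-based models in this
  setting (a +2.1 latent-SD shift with the default noise gives a
  univariate AUC ≈ 0.9);
* all four planted proteins must be recoverable by *both* engines at
  the fixed consensus thresholds (20% selection frequency, scaled mda
  > 8). The scaled mda of a protein that shares a high-correlation
  block with a stronger marker collapses (trees nearly always have the
  stronger partner available), so the default within-block latent
  correlation for blocks containing planted proteins is 0.55 rather
  than the ~0.8 observed between synaptic proteins in real CSF; the
  block structure (NPTX2–VGF–PTPRN2; AQP4–AMPH; an acute-phase block at
  rho 0.7) is retained qualitatively. The rank-correlation calibration
  property (Spearman → 6/π·asin(rho/2)) is exercised at configurable
  rho, including 0.85.

The generator does **not** model bead counts, antibody cross-reactivity,
censored/missing values, inter-plate interaction effects, or the
heavy-tailed outliers of real bead arrays beyond the log-normal noise;
passing recovery tests therefore demonstrate the correctness and
statistical behaviour of the selection machinery under the stated
generative model, not clinical validity on real cohorts.

## Normalization

Drift correction fits, per protein, a Huber M-estimated linear
regression of signal on readout position (tuning constant 1.345, MAD
scale about zero, IRLS, max 50 iterations, coefficient tolerance 1e-8)
and returns `residual − median(residual) + median(signal)`. Recentring
the residuals makes the operation exactly median-preserving and
idempotent to solver tolerance (plain residual + median is not, because
Huber residuals have nonzero median). Correction is applied on the raw
intensity scale by default with a log-scale option. Plate normalization
multiplies each plate's values by `global median / plate median` per
protein; plates with fewer than 3 samples are left unadjusted with a
warning.

## Stability LASSO

The penalized logistic path solver is IRLS with cyclic coordinate
descent and soft-thresholding (the standard penalized-GLM algorithm),
warm-started along a 100-point log-spaced grid from lambda_max down to
1e-3·lambda_max, with features standardized to population SD and an
unpenalized intercept. It was validated against glmnet (coefficients to
~1e-5, identical sparsity patterns) and against a proximal-gradient
oracle. Repetition r of the stability run uses CV fold seed
`base_seed + r`; since the training data are identical across
repetitions, the full-path coefficients are computed once and each
repetition selects its own lambda at the minimum mean held-out binomial
deviance (ties toward the larger, sparser lambda), exactly the
semantics of repeated `cv.glmnet` calls. Fold assignments are balanced
permutations; a fold whose training part is single-class triggers a
deterministic refold (max 10 attempts). Fold-path coefficient tolerance
is 3e-4 (only the CV curve is needed from the fold fits; the resulting
selection frequencies move by at most a couple of percent relative to a
10x tighter tolerance); the reported model uses 1e-6.
Linear predictors are clipped at ±30 when evaluating held-out deviance.

On strongly separated synthetic data the deviance-minimizing lambda is
often deep in the path, so many noise proteins reach high selection
frequencies; the consensus *core* is robust to this because it also
requires a forest importance that noise proteins essentially never
reach.

## Random-forest importance ensemble

Forests are fully grown CART trees (Gini, minimum node size 1,
bootstrap of n with replacement, `mtry = floor(sqrt(p))` features per
split), 500 trees per forest by default. The engine is a compact
numba-compiled implementation because the statistic needs per-tree
bootstrap membership: for each tree, OOB accuracy is compared with OOB
accuracy after permuting one feature's OOB values; unused features
contribute a decrease of exactly zero. Per forest, the mean decrease is
scaled by its standard error across trees (population SD / sqrt(ntree)),
the convention under which published mda values fall in the 5–30 range;
the raw accuracy scale is available by configuration. When the SD is
zero the raw mean (usually 0) is reported, with a warning for proteins
never used. The engine is cross-checked in the tests against sklearn
forests (OOB error/AUC) and against R randomForest's scaled
MeanDecreaseAccuracy (same top features, importance profiles correlated
> 0.9). Forest r of an ensemble uses seed `base_seed + r`.

`tune_forest` selects the tree count by OOB error over a user grid
(ties toward the smallest) and mtry by the classic doubling/halving
search around sqrt(p), accepting steps that improve OOB error by more
than 5% relative. The default configuration pins 500 trees — the
conventional forest size for this assay scale — and tuning is exercised
as its own operation; ensemble runs keep one fixed configuration, since
re-tuning inside a seed ensemble would confound the importance scale.

## Consensus and evaluation

Union = selection frequency ≥ threshold OR mean mda > threshold; core =
AND. Frequency is compared inclusively and mda strictly, matching the
wording "at least 20%" / "above 8". Evaluation conventions: positive
class = affected (or PMC); predicted positive at score ≥ cut-off; AUC by
the Mann–Whitney rank statistic with half credit for ties (equal to the
trapezoidal ROC area); the Youden cut-off maximizes sensitivity +
specificity − 1 with ties broken toward higher specificity and is taken
from the test-set ROC (a configurable choice — the train-derived
alternative is a one-line change at the call site).

## Downstream statistics

Wilcoxon rank-sum tests are exact (full enumeration) when the pooled
sample is ≤ 20 without ties, otherwise normal approximation with tie and
continuity corrections; identical pooled samples give p = 1. Spearman
matrices are Pearson correlations of midranks (constant proteins give
NaN with a warning). PCA uses natural-log intensities, centred and
unit-scaled per protein (correlation-matrix PCA; covariance PCA via the
`standardize` flag); variance explained is relative to the total across
all components and per-variable contributions are squared loadings in
percent. PC-space clustering is average-linkage (UPGMA) on Euclidean
distances over the first two score columns, cut into k = 3 clusters and
renumbered by increasing size; purity is the majority-class share,
rounded half-up for display with the raw fraction retained. Demographic
balance uses an exact Freeman–Halton test for 2×k sex-by-group tables
(enumeration over all tables with the observed margins — the scipy R×C
code path is resampling-based) and one-way ANOVA with Tukey HSD for age.

## Problem sizes used in the automated experiments

The recovery experiments run the full dual-selection pipeline at cohort
sample sizes (213 samples × 111 proteins) with R = 100 repetitions per
engine — a tenth of the production default of 1000, which leaves the
per-protein frequency and mean-mda estimates accurate to a few percent
— over 20 dataset seeds for recovery and 10 for the null control, and
the acceptance script repeats the end-to-end discovery on 5 cohorts.
All runs are pure functions of their seeds.

## Known limitations

* Scaled mda depends on the forest size (it grows like sqrt(ntree)), so
  the fixed consensus threshold of 8 is meaningful only relative to the
  ~500-tree default; the raw scale is provided for threshold-free use.
* The stratified split rounds half-up per class; published splits that
  deviate from exact 2/3 by one sample cannot be reproduced exactly.
* The plate-normalization method (median ratio) is one reasonable
  choice among several; a configurable hook (`PlateNormalizer`
  subclassing) is the intended extension point.
* The exact-enumeration Freeman–Halton test is practical for 2×k with
  small k only (the demographic use case).
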