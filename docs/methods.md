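# Methods

This note documents the statistical model behind `lagdml`, the synthetic
data-generating process the package validates itself against, the defaults
and numerical choices, and what the validation suite does and does not
establish.

## Panel model and estimands

Data are discrete-time panels: subject *i* observed at intervals
*t* = 0, …, T−1 with predictors X_{ijt}, an interval-level initiation
indicator y_{it} ∈ {0,1} per outcome, and an at-risk indicator m_{it}.
Initiation is absorbing: m = 1 up to and including the first event row and
0 afterwards, so each outcome defines a discrete-time hazard on its at-risk
set.  All modeling uses lagged copies `p_Lk` (value k intervals earlier,
never crossing subjects) and optionally change scores `p_D1 = p_L1 − p_L2`;
raw contemporaneous values never enter a model, which is what gives the
discovered edges their temporal direction.

Stage 1 is predictive screening: an edge (p_Lk → y) is proposed when the
elastic net retains p_Lk while predicting y from all lagged predictors
jointly, consistently across subject-level bootstrap resamples.  Stage 2
targets, for each stable edge, the linear-projection coefficient θ of the
residualized outcome on the residualized treatment.  When the hazard is
linear in the standardized treatment on the probability scale, θ equals
the average effect of a +1 SD intervention on the lagged predictor; under
a logistic hazard with modest coefficients it approximates the average
derivative effect.  θ is causal only under the usual assumptions: correct
temporal ordering, and confounding captured by the lagged covariate set.

## Synthetic generator

The generator (`lagdml.simulate`) emulates the structure of a large
adolescent-cohort panel without reproducing any real measurement model:

- **Predictors**: Gaussian, stationary AR(1) in time (default
  autocorrelation 0.6 — persistent but clearly time-varying), cross-
  sectionally equicorrelated in blocks (default block size 10, within-block
  correlation 0.3), mimicking domains of related instruments.
- **Confounding**: one latent standard-Gaussian trait U per subject,
  constant in time, loading (default 1.0) on a configurable predictor
  subset — by default the causal predictors plus an equal number of pure
  proxies — and additively with weight `confounder_strength` on each
  hazard's linear index.  This is the simplest structure that forces the
  estimation stage to remove confounding it can only observe through
  proxies and the treatment's own past.
- **Hazards**: per-interval probability σ(α + Σⱼ βⱼ Z_{ij,t−1} + γU) with
  Z the standardized predictor; true edges are lag-1 (a config switch adds
  lag-2 edges for stress tests).  At step 0 no history exists, so only
  α + γU acts.  A `hazard_model="linear"` variant puts the same index on
  the probability scale (clipped to [10⁻⁴, 1−10⁻⁴]) so that θ equals the
  generating coefficient exactly — the natural setting for calibration
  studies.  Default intercepts put per-interval hazards in the rare-event
  range (cumulative initiation roughly 3–40% over five intervals);
  generation fails loudly if an outcome's empirical per-interval hazard
  reaches 0.5.
- **Defaults**: 10,000 subjects × 5 intervals × 200 predictors with 5
  lag-1 effects of magnitude 0.5–0.8 log-odds per SD, alternating sign,
  placed one per correlation block so each signal has correlated null
  neighbours without signals being collinear.  Missingness is injected
  completely at random (default 5%), matching what median imputation
  assumes.
- **Oracle**: the true adjusted effect of an edge is computed by Monte
  Carlo — fresh subjects from the generating law, difference in event
  probability under a +1 SD shift of the lagged standardized predictor
  with U and everything else held at generated values, averaged over
  at-risk rows with enough history (≥ 10⁴ draws; a standard-error estimate
  is available).

What the generator does **not** emulate: informative dropout, survey
weights, measurement error, site/family clustering beyond the single
latent trait, non-Gaussian or categorical predictors, and calendar-time
effects.  Passing tests therefore demonstrate that the machinery is
correct under its stated assumptions, not that those assumptions hold in
any particular cohort.

## Stage 1 choices

- **Penalty.** The elastic-net penalty is parameterized per sample
  (λ · n · penalty(w) added to the summed log-loss).  The default selects
  λ once on the full eligible data by subject-grouped 3-fold
  cross-validated log-loss over a small grid, taking the **largest λ within
  one standard error of the best** (the glmnet "1-SE" convention), then
  holds it fixed across all bootstrap replicates.  Per-replicate tuning
  would confound selection stability with tuning noise; the 1-SE rule keeps
  replicate models sparse, which is what makes stability scores
  informative.
- **Mixing.** `l1_ratio = 0.5` splits the penalty evenly between sparsity
  and the ridge component that spreads weight over correlated predictors.
- **Bootstraps.** Default 100 (stability resolved to 0.01); resampling is
  at the subject level and a resample always contains whole subjects.  A
  replicate whose resampled outcome is constant is redrawn, up to 10
  attempts, then the run errors naming the outcome — silently skipping
  would bias the stability denominator.
- **Selection threshold.** A coefficient counts as selected when
  |β| > 10⁻⁸ on the standardized scale, guarding against solver round-off.
- **Class imbalance.** Balanced class weights by default (events are
  rare); configurable off.
- **Preprocessing.** Coerce to numeric, treat non-finite as missing,
  impute the column median (fallback 0 when a column has no observed
  value), z-score; constant columns map to all-zero.  Statistics are
  recomputed on whatever rows are being fitted (each bootstrap replicate,
  each estimation set) and stored so the identical transform can be
  replayed on held-out rows.
- **Solver.** saga with tolerance 10⁻³ and ≤ 500 iterations by default —
  selection events are insensitive to tighter tolerances at these sample
  sizes, and the bootstrap loop dominates runtime.

## Stage 2 choices

- **Covariates.** All lagged columns up to `max_lag` except the treatment
  column itself.  Other lags of the treatment variable stay in the
  covariate set by default: the treatment's own past is a legitimate
  confounder proxy and removing it would reopen the back-door through
  predictor autocorrelation.  A switch (`exclude_all_treatment_lags`)
  implements the stricter reading.
- **Cross-fitting.** Subjects are partitioned into `n_folds = 5` folds by
  a seeded permutation (round-robin), so folds are reproducible from the
  seed; sklearn's GroupKFold is deterministic and ignores seeds, which
  would make distinct runs identical by accident.  Every run asserts that
  no row is scored by a model trained on its own subject.
- **Nuisances.** Regression-mode random forests for both E[Y|X] (binary Y)
  and E[D|X]; defaults 500 trees, unlimited depth, min-leaf 5, all
  features.  A `linear` learner (OLS) is available and is the right choice
  when the hazard is linear.  Validation scenarios use reduced forests
  (tens of trees, depth ≤ 8, feature subsampling) — at n ≈ 6,000 rows the
  residualization quality saturates well below the production defaults.
- **θ regression.** No intercept by default: residuals are approximately
  centered by construction, and the closed form θ = ΣD̃Ỹ/ΣD̃² is exact and
  testable; an intercept is available via config and uses the matrix
  sandwich.
- **Inference.** Cluster-robust sandwich variance with the G/(G−1)
  small-sample factor (G = subjects), normal-quantile CIs — cluster counts
  in the target regime are in the thousands, where t and normal quantiles
  coincide to three decimals.  Degenerate cases error loudly: a single
  cluster, or ΣD̃² = 0 (treatment fully explained by covariates).
- **Estimation split.** Subjects (never rows) are split 80/20 into an
  estimation side and an untouched holdout by default; discovery and
  estimation both run on the estimation side so no selection information
  reaches the holdout.  Validation scenarios set the holdout to 0 because
  they compare against a simulation oracle rather than held-out fits.

## Validation design

The suite validates each guarantee under a fixed named scenario
(`lagdml.scenarios`); scenario parameters are part of the design, chosen
for the property each isolates, and only seeds vary:

- **Cohort arithmetic** reproduces the four published initiation
  percentages of the reference analytic cohort (N = 11,868) exactly from
  their counts, with 3-significant-figure rounding.
- **Closed forms** are property-tested against independent oracles:
  θ against `numpy.linalg.lstsq`, the sandwich SE against a brute-force
  sum over clusters and against the HC estimator in the singleton-cluster
  limit (both to 10⁻¹⁰).
- **Debiasing** uses the confounded logistic scenario (2,000 subjects × 5
  intervals, 10 predictors, confounder strength 1.0, treatment effect +0.5
  log-odds/SD): over 100 replicates the DML estimate must be closer to the
  Monte-Carlo oracle than the naive lagged slope in ≥ 90.
- **Coverage** uses the linear-hazard scenario (15 predictors, effects
  ±0.02 on the probability scale, no latent confounder, linear nuisances):
  the 95% CI must cover the oracle in 90–99% of 200 replicates.  The
  confounder is off here deliberately — the check isolates the sampling
  calibration of the cross-fitted estimator and its clustered variance; a
  latent trait observed only through proxies adds a bias no partialling-out
  estimator can fully remove, which is the debiasing scenario's subject,
  not this one's.
- **Edge recovery** uses the 100-predictor calibration panel (5 true lag-1
  effects, |β| ≥ 0.5, one per block, 50 bootstraps, no latent confounder):
  across 10 seeds every true edge must reach stability ≥ 0.8 and exceed
  the 90th percentile of null stabilities.  With a strong latent trait,
  proxy predictors would be genuinely predictive non-causal edges and the
  causal/null contrast would be ill-posed — predictive discovery is
  working as designed when it finds them.
- **Hygiene** checks run everywhere: truncating a subject's future leaves
  all lags bit-identical; fold partitions never mix a subject across
  folds; the at-risk filter retains no post-initiation rows.

Problem sizes in the validation suite (replicate counts, predictor counts,
forest sizes) are the scenarios' own definitions, kept at desk scale so
the whole suite runs in minutes on one CPU.

## Known limitations

- θ is a projection estimand; under a logistic hazard with strong effects
  it differs from the average-derivative effect by a curvature term
  (visible as a ~0.005–0.01 offset in the confounded demo).
- Latent confounding is only removed to the extent the covariates proxy
  it; the residual bias shrinks with the number of proxies and with the
  treatment's own lags in the covariate set but does not vanish.
- Median imputation is defensible only under (near-)MCAR missingness;
  informative missingness will bias both stages.
- No multiple-testing control is applied across the discovered edge set;
  stability scores and per-edge CIs should be read jointly, not as
  family-wise guarantees.
- Stability selection inherits the elastic net's behaviour under masking:
  a causal predictor whose marginal association is cancelled by an
  opposing confounder path can be missed in discovery even though the
  estimation stage would recover its adjusted effect.
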