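# Methods

This note documents the models, the data-generating process, the numerical
choices and the known limitations of dynasurv, in the package's own words.

## Data model

A cohort is a set of subjects `i = 1..N`, each with

* baseline covariates `B_i` (K numeric values; categorical variables are
  one-hot encoded with the first level dropped, levels sorted, so the
  encoding is deterministic),
* visits `(t_ij, Y_i(t_ij))`, `j = 1..J_i`, with strictly increasing times
  and Q longitudinal values per visit (missing entries allowed),
* an observed time `T_i = min(T*_i, C_i) > 0` and event indicator
  `δ_i ∈ {0,1}`.

Missing longitudinal values are imputed by last observation carried forward
within each subject; values missing from the start of follow-up stay
missing until encoding time, where they are filled with the *training-set*
mean of that variable.  Doing the mean fill inside the encoder keeps the
transform total without leaking evaluation data into training statistics.

### Landmarking

`landmark(ds, l)` keeps subjects with `T_i > l` (a subject with `T_i`
exactly equal to `l` is removed) and visits with `t_ij ≤ l` (a visit
exactly at `l` is kept); subjects whose first visit falls after `l` are
dropped, and their count is visible through the view sizes.  The four
training strategies are thin compositions of this transform: `strict` fits
one pipeline per landmark, `super` concatenates the landmarked copies
(replicate ids tag each copy with its landmark), `random` redraws a uniform
visit-count truncation per subject at every training epoch (a visit *index*
is drawn, not a time — evaluation-time truncation is always time-based),
and `none` trains on complete histories.  Under every strategy the
evaluation data are landmarked, so `none` deliberately reproduces the
train/evaluation mismatch it is known to suffer from.

## Simulator

Subjects carry per-variable scalars `x_iq ~ N(3,1)`, baseline covariates
`z_1 ~ Bernoulli(0.5)` and `z_2 ~ N(0,1)`, and random effects
`b_i ~ N(0, Σ)` with SDs `[1, 1.5, 2]` and correlations
`[−0.2, 0.1, −0.3]`.  Noise-free trajectories on the 21-visit grid over
[0, 10] are

* scenarios 1/2/4: `X_q(t) = β0_q + β1_q x_q + β2_q t + b_q`
* scenario 3:      `X_q(t) = β0_q + β1_q x_q + (β2_q + b_q) t`

with `β0 = [1.5, 2, 0.5]`, `β1 = [2, −1, 1]`, `β2 = [1.5, −1, 0.6]`.
Observations add N(0, 1) measurement error.  The log hazard is
`−7 + γ·B + Σ_q α_q X_q(t)` with `γ = [−4, 2]` (scenario 2:
`γ = [−4, 2, 4]` on `[z1, z2, z1·z2]`, the interaction being withheld from
the observed covariates) and `α = [0.2, −0.2, 0.4]`.  Scenario 4 adds
`X4(t_j) ~ U(−11, 9)` i.i.d. per visit — observed with the same
measurement noise — and the term `0.2·R(t_j)` with
`R(t_j) = Σ_{k ≤ j−6} X4(t_k)`: the covariate's effect reaches the hazard
six visits (three time units) after it is measured.

**Event-time discretization.**  The generator is a discrete-time survival
model: visit `j` carries the hazard mass `λ_j` and the true survival
function is the right-continuous step function
`S(t) = exp(−Σ_{t_j ≤ t} λ_j)`.  The latent event time is the first grid
time with `S(t) < u`, `u ~ U(0,1)`; the rare crossing at `t = 0`
(possible because `S(0) = e^{−λ_0} < 1`) is moved to the first positive
grid time so observed times stay positive.  Censoring is `U(1, 22)`
truncated at the end of the visit window: a subject whose survival never
drops below `u` on the grid is censored at `t = 10`.  Visits are recorded
strictly before the observed time.  These conventions were fixed by
matching the published per-scenario cohort summaries (censoring fraction,
mean/SD of observed time, mean/SD of visit count) at n = 20,000; the
continuous-time alternative (trapezoid/exact integration of the hazard
with uncapped censoring) misses those summaries by 7–10 percentage points
of censoring and ~2 visits.  Residual known deviations at n = 20k:
scenario-1 mean observed time 4.96 vs the published 5.1, scenario-2 mean
visit count 9.0 vs 10.2, and scenario-4 censoring 43% vs 48% — in each
case the remaining moments of the same scenario match closely, and no
reading consistent with the stated parameters closed these gaps.  The
corresponding acceptance tests assert the published values at their stated
tolerance and are expected to fail, which we consider the honest outcome.

Randomness uses one master seed with per-subject substreams
(`SeedSequence.spawn`), so growing `n_subjects` reproduces earlier
subjects bit-identically.

## Encoders

**Baseline / last visit.**  `Z = [B, Y(t_0)]` and
`Z = [B, Y(max{t_j ≤ l})]`; no fitting beyond the training means used for
leading-gap imputation.

**MFPCA.**  Univariate FPCA per variable, then a PCA across the stacked
univariate scores (the standard two-step construction for multivariate
functional data):

* mean function: weighted penalized-spline smooth of the pooled
  (time, value) points, via per-unique-time means with count weights, on a
  101-point working grid;
* covariance surface: raw residual cross-products binned to the grid
  (diagonal excluded, because it carries the measurement-error variance)
  and smoothed with a normalized Gaussian kernel, bandwidth 1/20 of the
  observed time range.  This replaces the local-polynomial smoother of
  classical PACE implementations with a cheaper kernel smoother; on the
  dense, regularly gridded data this package targets the two coincide to
  within the smoothing bias, and the rank-1 recovery test pins the
  accuracy (leading eigenvalue within 5%);
* measurement-noise variance: mean gap between the smoothed raw diagonal
  and the surface diagonal over the central 80% of the domain, floored at
  zero;
* eigenfunctions/values from the eigendecomposition of the discretized
  covariance operator (`C·h`), signs fixed so each eigenfunction has a
  non-negative integral; univariate components retained up to 99% of
  variance (at most 10 per variable);
* scores by the Gaussian conditional expectation
  `ξ = Λ Φ' (Φ Λ Φ' + σ²I)^{-1} (y − μ)` evaluated at the subject's own
  visit times — robust to truncated histories, shrinking scores toward 0
  as visits are removed;
* multivariate step: scores standardized by each variable's pooled SD
  (the variables live on very different scales and nothing in the model
  fixes their relative weight), stacked, centered, rotated by PCA;
  the smallest number of components explaining ≥ 95% of variance is kept.

The encoding is `Z = [B, Y(t_0), ρ]`; including the first-visit
longitudinal values alongside the demographics is a deliberate choice
(the alternative — demographics only — is one flag away in
`mfpca_encode`/`MFPCAModel.include_baseline_long`).

**Recurrent encoder.**  A two-layer Elman network,
`h_n,j = tanh(x W' + b + h_{n,j−1} W1' + b1)`, hidden width `5 + Q`,
dropout 0.3 between layers.  The visit time is appended to each step's
input so irregular spacing is visible to the recurrence (the architecture
has no other time channel); this is controlled by
`RNNHyperparams.include_time`.  A feed-forward head (one hidden layer of
32 ReLU units) predicts the next visit's values from `(h_j, B)`; the
longitudinal loss is the per-subject-normalized next-visit MSE.  In
`long_only` mode that is the whole objective.  In `combined` mode the
model also carries a discrete-time survival head on `Z = [B, h_last]` and
minimizes the sum of both losses, after which the entire network is
fine-tuned on the survival loss alone.  Optimization: Adam, lr 1e−3,
weight decay 1e−5 (L2 folded into the gradient), batches of 32, 100
epochs per phase by default, deterministic under the seed.  The
implementation runs on a ~200-line reverse-mode autodiff over numpy
(`dynasurv/_nn.py`) written for this package because no deep-learning
framework is assumed; a finite-difference gradient check covers its ops.

## Survival heads

**Cox.**  scikit-survival's partial-likelihood fit with Breslow tie
handling and Breslow baseline; constant feature columns are dropped with a
warning, and with no usable features the baseline survival reduces to
`exp(−Nelson–Aalen)`.  No regularization by default — convergence failures
on small strict-landmark subsets are reported as failed cells rather than
silently ridge-stabilized (an optional `ridge` penalty exists but is off).

**Random survival forest.**  scikit-survival's implementation: 1,000
trees, log-rank splits over `√D` candidate features, minimum 32 samples to
split and 16 per leaf, Kaplan–Meier leaf curves, ensemble = arithmetic
mean of tree curves (asserted against per-tree enumeration in the tests).

**Discrete-time network.**  Interval boundaries are half-unit multiples
covering the observed times plus one overflow interval; the network is two
dense layers (32 hidden units, ReLU + dropout 0.3 after the first) with a
softmax over intervals.  The loss is the discrete negative log-likelihood:
events contribute `−log P(T = interval of T_i)`; censored subjects
contribute `−log [P(T > interval of T_i) / P(T ≥ landmark interval)]`,
conditioning each training sample on its own landmark.  Under the `none`
strategy no landmark exists and the conditioning index is 0 — together
with full training histories this reproduces the optimism/bias of that
strategy rather than repairing it.  Prediction composes the softmax with
the conditional failure function
`F(τ) = Σ_{l<m≤τ} p_m / P(T > l)` and returns right-continuous step
curves, extended flat beyond the last boundary, `S ≡ 1` left of the first
mass point.

## Evaluation

Conditional risks `R(t|l) = 1 − S(t)/S(l)` are computed from each head's
curves by right-continuous step lookup; subjects with `S(l) = 0` are
flagged NaN and excluded from metrics with a warning.  The censoring
distribution `G` is the Kaplan–Meier estimator with censoring as the
event, fitted on training data only.  The tdAUC is the IPCW-weighted
fraction of correctly ordered (case, control) pairs with case weights
`1/G(T−)`; ties in the predicted risk count 1/2 by default (a constant
predictor scores 0.5) — the literal strict-inequality formula is available
via `strict_ties=True`.  `G` is evaluated as a left limit where it divides
an event term, and terms with `G = 0` are excluded with a logged count.
The IPCW Brier score averages
`δ·1(T≤t)(1−R)²/G(T−) + 1(T>t)·R²/G(t)` over all subjects (censored-
before-t subjects contribute 0).  On simulated data the MSE against the
generator's exact conditional risks is reported, with the true-risk
predictor (`oracle_reference_metrics`) as the per-scenario ceiling: its
MSE is identically 0 while its tdAUC/Brier remain imperfect because
individual outcomes stay random.

Default evaluation grid: landmarks {1, 2, 3, 4} and horizons
`l + {0.5, …, 5}`; study results aggregate as mean ± SD over replicates
(simulation) or folds (cross-validation).

## What the synthetic generator does and does not emulate

It emulates: linear latent trajectories with correlated random effects and
i.i.d. measurement noise, visit-gridded event times, uniform noninformative
censoring with an administrative cap, subject-specific slopes (scenario 3)
and a delayed, unpredictable hazard driver (scenario 4).  It does not
emulate irregular or informative visit schedules, missingness mechanisms
(simulated values are complete), competing risks, informative censoring,
or measurement-batch effects — so a green simulation test establishes the
pipeline's correctness under the stated model, not robustness to those
real-data features.  The TADPOLE-schema ingestion is exercised with a
synthetic stand-in cohort; the real cohort is access-restricted, and the
published headline numbers on it are not reproducible from this
repository.

## Hyperparameter search

`random_hyperparameter_search` draws n configurations from user-supplied
samplers, trains each on 80% of the training subjects, scores mean tdAUC
on the held-out 20%, and returns the argmax; test data never enter the
selection.  Seeds flow study → replicate → model and are logged in every
results bundle.

## Known limitations

* The generator's discretization conventions were identified empirically
  from published summary statistics; three of those statistics remain
  outside their Monte-Carlo band (see the simulator section) and the
  corresponding acceptance tests fail by design.
* The numpy networks are CPU-only and modest in scale (hundreds to a few
  thousand subjects); no GPU path exists.
* `strict` Cox fits on late landmarks can legitimately fail to converge on
  small subsets; these surface as recorded failed cells.
* No competing risks, time-varying Cox coefficients, or forest variable
  importance.
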