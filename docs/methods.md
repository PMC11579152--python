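# Methods

`thetanav` classifies participants of a virtual water-maze task as
learners or non-learners from two per-subject, per-trial data streams:
the frontal-midline theta-power time series recorded while navigating,
and the x–y arena trajectory sampled every 0.25 s.  The package covers
the full path from raw series to evaluated classifiers: standardisation,
two model-based EEG feature extractors (a Gaussian hidden Markov model
and a peak-curvature linear mixed model), four trajectory summaries,
leave-one-out evaluation of six classifier configurations, and
local-surrogate explanations of individual predictions.

## Models

### Gaussian hidden Markov model (per series)

Each theta series \(x_1..x_T\) is modelled with a latent first-order
Markov chain \(C_t \in \{S_1..S_M\}\) (transition matrix \(P\), initial
distribution \(\delta\)) and state-conditional Gaussian emissions
\(X_t \mid C_t \sim N(\mu(C_t), \sigma^2(C_t))\).  Emissions are
conditionally independent given the state path: the serial dependence of
the observed series is carried entirely by the chain.  The free
parameter count is \(M^2 + 2M - 1\) (M means, M variances, M(M−1)
transition entries, M−1 initial probabilities), used in
\(\mathrm{AIC} = -2\ell + 2(M^2+2M-1)\).

Fitting is Baum–Welch EM with scaled forward–backward recursions
(per-step renormalisation; log normalisers accumulated, so long series
never underflow).  Design choices:

* **Initialisation / restarts.** Means start at the series quantiles
  \((k+0.5)/M\) plus seeded jitter (SD = 0.1 × series SD), variances at
  the sample variance, transitions and \(\delta\) uniform; 5 restarts by
  default, best log-likelihood kept.
* **Convergence.** Relative log-likelihood change < 1e-8 or 500
  iterations.  EM monotonicity is asserted at every iteration; a
  decrease beyond numerical slack raises an error rather than being
  silently accepted.
* **Variance collapse.** State variances are floored at 1e-6 × the
  sample variance and the fit is flagged, so a state shrinking onto a
  single observation cannot drive the likelihood to infinity.
* **Label switching.** State labels are arbitrary under the likelihood,
  so after fitting the states are put in canonical order — ascending
  mean, ties broken by ascending variance.  Without this, "state 2's
  mean" would not be comparable across subjects and the per-state
  features would be meaningless as classifier inputs.
* **Decoding.** State occupancy frequencies come from the Viterbi path
  (jointly most probable sequence); expected posterior occupancy is
  available as an alternative (`occupancy="posterior"`).

The per-subject feature vector at the default \(M=4\) is the 4 state
means, 4 state variances and the first 3 occupancy frequencies (the
fourth is one minus the rest): 11 features.  The M(M−1) free transition
probabilities can be appended (`include_transitions=True`); they are off
by default to keep the 11-feature set.  `aic_profile` refits each series
over a grid of M (default 2–5) to support choosing the state count.

### Peak-curvature linear mixed model (per trial dataset)

From each standardised series, every interior local maximum contributes
a peak height \(y_{ij}\) (the value at the peak) and a curvature
\(x_{ij} = x_{k-1} - 2x_k + x_{k+1}\) (second-order difference; negative
at a strict peak, and kept signed).  A plateau whose value exceeds both
sides contributes its first index only; endpoints are never peaks.
Pooling subjects within one trial dataset, heights are regressed on
curvatures with per-subject random intercepts and slopes:

    Y_ij | b_0i, b_1i ~ N(b_0i + b_1i x_ij, sigma^2)
    b_0i ~ N(beta_0, sigma_0^2),  b_1i ~ N(beta_1, sigma_1^2),
    Corr(b_0i, b_1i) = 0

The diagonal random-effects covariance is a model constraint, not an
estimate.  Estimation maximises the closed-form Gaussian marginal
likelihood (ML by default, REML optional) over
\((\beta_0,\beta_1,\sigma^2,\sigma_0^2,\sigma_1^2)\): variances are
optimised on the log scale by Nelder–Mead with the fixed effects
profiled out by GLS at each step.  All per-subject quantities reduce to
2×2 algebra through the Woodbury and push-through identities (valid when
a variance component is estimated at zero), so likelihood evaluations
cost O(subjects) whatever the peak counts, which keeps the per-fold
refits inside cross-validation cheap.

The classifier features are the empirical-Bayes predictions (BLUPs)
\(\hat b_{0i}, \hat b_{1i} = \beta + D X_i^\top V_i^{-1}(y_i - X_i\beta)\):
each subject's own regression line shrunk toward the population line in
proportion to how little data the subject contributes.  A subject with
no peaks receives the population values; subjects with < 2 peaks are
retained but logged.  One model is fitted per trial dataset (both groups
pooled, trials separate), since classification is per-trial.

**Leakage control.** By default the mixed model is refitted inside every
leave-one-out training fold; the held-out subject's BLUP is computed
from the trained parameters plus its own peaks only, so its group label
never touches training.  A fit-once mode (`lmm_mode="fit_once"`)
reproduces the simpler protocol in which the model is estimated once on
everyone.  Fold refits are warm-started from the full-data variance
estimates and shared across classifiers.

### Trajectory features

Per subject × trial, on the 0.25 s grid: total idle time (steps with
displacement ≤ eps, default eps = 0), total path length (summed
Euclidean step lengths, Vm), total angle shift (summed absolute heading
change in degrees), and average speed (path length / trial duration,
Vm/s).  Headings use the four-quadrant arctangent `atan2(dy, dx)` rather
than the one-argument arctangent of a slope ratio, which is undefined
for vertical steps and conflates opposite directions; heading
differences are wrapped to [0°, 180°] so a turn and its mirror count
equally; zero-displacement steps have no heading and are skipped.

### Standardisation

Three per-series scalings of the theta trace are compared: raw, minmax
\((x_t-\min)/(\max-\min)\), and z-score \((x_t-\bar x)/s\) with the
sample (n−1) SD.  Statistics are computed within each subject × trial
series — never pooled across subjects — which matches the per-series
definition of the transforms and avoids cross-subject leakage under
LOOCV.  Constant series are rejected as degenerate.

## Classification and evaluation

Three feature tables per (trial, standardisation): `eeg` (11 HMM + 2
LMM features + series duration), `coordinates` (the 4 trajectory
features), `combined` (their column union).  Six classifier
configurations:

| name | configuration |
|---|---|
| poly_svm | SVM, 3rd-order polynomial kernel |
| rbf_svm | SVM, RBF kernel, gamma = 1/(n_features · feature variance) |
| random_forest | 1000 trees, depth 5 |
| knn | 1 nearest neighbour |
| elastic_net_logistic | penalty λ[α‖β‖₂² + (1−α)‖β‖₁], α = 0.98 (L2-dominant), λ = 1 |
| dnn | MLP, hidden layers 100-150-200-150-46-20-10, sigmoid output |

Unprinted choices are defaults and logged: SVM scores are signed
margins, probabilistic models score with the positive-class
probability; the MLP uses ReLU hidden units, binary cross-entropy, the
adaptive-moment optimiser at learning rate 1e-3 for 200 full-batch
epochs (loss-plateau early stopping disabled so the configured epoch
count actually runs), seeded initialisation.  Features are centred and
scaled by training-fold statistics for the scale-sensitive learners
(SVMs, KNN, elastic net, MLP); the random forest sees raw features.

Evaluation is leave-one-out cross-validation with a single AUROC
computed from the n pooled held-out scores (Mann–Whitney form, ties ½).
Pooled-score AUROC was preferred over fold-averaged variants because a
one-subject fold has no AUROC of its own.

## Local surrogate explanations

For each subject, the trained classifier's continuous score is probed
with 500 Gaussian perturbations of the subject's feature vector
(per-feature SD = 0.25 × the cohort SD), weighted by an exponential
kernel on standardised Euclidean distance (width 0.75·√p).  K-Lasso
fits the sparse local surrogate: LARS selects K = 3 features, a
kernel-weighted least-squares refit gives their coefficients, reported
on the original feature scale so a linear scorer's weights are recovered
exactly.  Constant features (e.g. the capped trial-1 duration) carry no
perturbable signal and are dropped with a log line.  Rankings aggregate
per (group, trial): features ordered by how many subjects selected them,
ties by mean absolute weight.

## Synthetic cohorts

The generator produces cohorts with the statistical structure the method
assumes, so every stage is testable without any data download.  Defaults
emulate the study design: 25 subjects per group, trials 1 and 12, a 60 s
trial cap, theta at 4 Hz (the extractors are sampling-rate agnostic;
4 Hz keeps tests fast and is configurable), a 75 Vm-diameter circular
arena with a centred hidden goal occupying 15% of the arena area, and a
fixed start on the rim.

* **Theta.** Drawn from group × trial Gaussian HMM truths.  Trial-1
  truths are identical across groups (neither group has learned
  anything on first exposure); the learner trial-12 truth moves each
  state mean outward by 3 within-state SDs — a non-affine contrast
  chosen to force separation that survives per-series standardisation —
  with state-dependent variances and higher chain persistence (diagonal
  0.92 vs 0.80).
* **Trajectories.** Correlated random walks (per-step Gaussian heading
  increments, per-step idle probability, constant speed 4.76 Vm/s as in
  the task).  Learner trial-12 walkers rotate 10% of the bearing error
  toward the goal per step and stop on entering it; every other cell
  walks unbiased for the full duration.  Goal termination applies only
  to goal-knowing (biased) walkers, so trial-1 durations are
  group-identical.  Non-learner durations are matched to the mean
  learner duration of the same trial, as in the experimental design.  A
  12 s duration floor keeps every theta series long enough for an M=4
  fit (≥ 10·M observations).
* **Forced-separation construction.** `separated_cohort_spec()` is the
  cohort used for end-to-end validation: the same design but with a
  crisper baseline (emission SD 0.05 against 0.4 state spacing), a
  learner trial-12 truth whose state means move outward by several
  within-state SDs with halved/doubled variances and chain persistence
  0.95 vs 0.85, and a 30 s duration floor so every series supports a
  stable four-state fit.  Its purpose is diagnostic: under truths this
  separated, a correct pipeline must classify trial 12 almost perfectly
  while trial 1 — generated as a pure null — stays at chance.  The
  effect size is deliberately chosen to force separation; it is a
  validation instrument, not a claim about realistic effect sizes.
* **Truth records.** Generating parameters and hidden state paths are
  always returned; parameter-recovery tests are the primary acceptance
  surface because the study's human-cohort results are not reproducible
  from summary numbers alone.

What the generator does **not** emulate: 1/f EEG background, wavelet
autocorrelation of theta power, wall-collision kinematics, or
inter-trial learning curves.  Passing tests therefore demonstrate that
the pipeline recovers structure *of the assumed form* and reproduces the
trial-1-vs-trial-12 classification signature when that structure is
present — not that human EEG satisfies the model.

## Numerical choices and degenerate inputs

* Scaled (not log-space) forward–backward with per-step normalisers;
  Viterbi in log space with ties broken toward the lowest state index.
* HMM fits require series length ≥ 10·M (rule of thumb, configurable).
* Constant series: standardisation raises a degenerate-input error.
* Angle shift requires ≥ 2 moving steps; idle steps never contribute a
  heading.
* LMM optimisation: log-variance parameterisation, Nelder-Mead,
  convergence 1e-8 on relative log-likelihood; variance estimates are
  non-negative by construction.
* All randomness flows from one integer seed, fanned out to named
  CRC-derived substreams (stable across processes), so cohort
  generation, EM restarts, classifier initialisation and explanation
  perturbations are independently reproducible.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the method at the study's
cohort size (25 per group, both trials) with theta at 4 Hz, EM recovery
at T = 2000 over 20 replicates, mixed-model recovery at 50 subjects ×
30 peaks, exhaustive-enumeration oracles at M ≤ 3, T ≤ 8, and the
explanation check at 500 perturbations — sizes at which the oracles are
exact and the Monte-Carlo bands quoted in the tests hold.

Two checks are deliberately replicated rather than single-draw, because
at n = 50 a single draw is itself noisy: the mixed-model fixed-effect
coverage uses the median z-score over 3 replicate simulations (one draw
of 50 random effects can sit 3 SDs from the population truth), and the
trial-1 chance-level AUROC uses the median over 3 independent null
cohorts (pooled-LOOCV AUROC under the null has an SD of roughly 0.1 at
this cohort size, and is not exactly centred on 0.5 because each
held-out subject's training fold is slightly unbalanced against its own
class).

## Known limitations

* One HMM per series: no population-level sharing of states across
  subjects, so state identities align across subjects only through the
  ascending-mean convention.
* The mixed model uses a single covariate (curvature) and uncorrelated
  random effects by construction.
* AUROC on 50 subjects has a wide sampling distribution; differences of
  a few points between classifier configurations are not meaningful at
  this n.
* The MLP trains 10^5 weights on 49-subject folds; its LOOCV scores
  vary with initialisation seed, which is why every evaluation records
  its seed.
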