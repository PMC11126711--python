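# Methods

## Generative task design

`TaskConfig` defaults encode the study conditions: 8 blocks of 20 trials;
box→token transition probabilities of 0.8 (low observational uncertainty)
or 0.6 (high), constant within a block, near-balanced across blocks; token
reward probabilities of 0.8 or 0.6, complementary between the two tokens at
every trial; exactly one within-block reversal of the valuable token plus a
forced flip at every block boundary; reward magnitudes uniform over
[45, 55] points in narrow-variance blocks and [1, 99] in wide-variance
blocks (unrewarded outcomes are 0 points); 16 deterministic trial lists per
seed; token and box screen positions randomized per trial.

Choices where the original design left latitude, made once and fixed:

- **Reversal position.** One reversal per block is specified but not its
  position; it is drawn uniformly over trials 8–13 of the block (0-based),
  which guarantees at least 7 post-reversal trials for the learning-curve
  analysis.
- **Reward-contingency segmentation.** Experiential uncertainty varies
  within blocks; each block is split into two 10-trial segments whose
  0.8/0.6 contingency level is drawn independently (configurable via
  `segments_per_block`).
- **Between-block reversals.** The valuable token flips at every block
  boundary by default (`flip_between_blocks`).
- **Partner at a reversal.** The partner knows the valuable token, so at a
  reversal its box values are reflected (`v ← 1 − v`): the box→token
  mapping is unchanged while the goal flips, and an informed agent
  re-targets instantly. Relearning from 0.5 is available as
  `relearn_at_reversal`.
- **Missing responses.** The generator never emits them; the CSV reader
  accepts them and flags sessions missing more than 25% of choices (the
  exclusion threshold used for human data) without enforcing exclusion.

## Trial timing inside the models

Each trial has an observation phase followed by a choice phase. The
observational update (transition-probability delta rule with counterfactual
update, clipped to [0, 1]) runs **before** the participant's choice, on the
current trial's box–token pair, because the partner is observed first; the
experiential update runs **after** the outcome. Consequently the dynamic
arbitration weight uses the current trial's `|oSPE|` but the previous
trial's `|eRPE|` and outcome magnitude. Token values start at 0.5;
magnitude trackers start at 0 (no reward history exists); box values reset
to 0.5 at each block start (new fractal pair) while token values carry
across blocks. On a missed choice the experiential update is skipped (no
outcome was experienced), the trial is excluded from the likelihood, the
own-side history used by the baseline model becomes undefined, and the most
recent experienced prediction error and outcome continue to feed the
reliability terms.

## Reliability normalization

Both prediction errors are differences of probabilities/indicators, so
their unsigned values lie in [0, 1]; min–max normalization uses these
theoretical bounds by default (`NormalizationPolicy`). Theoretical bounds
are causal (usable during generation) and deterministic; empirical
whole-session bounds are available as an option, with degenerate bounds
(max = min) falling back to reliability 0 with a warning.

## Model fitting

Per subject and model, MAP estimation in unconstrained space — sigmoid for
learning rates and the mixture weight, exp for inverse temperatures,
identity for the magnitude-boost μ, the arbitration bias δ, and the
baseline biases — under independent N(0, 6.25) priors. L-BFGS with
six restarts (one at the prior mean, five prior draws; the likelihoods are
multimodal but low-dimensional, and restart stability was verified — the
best objective is reproduced by independent restart sets), objective
tolerance 1e-6. Log evidence is the Laplace approximation at the mode with
a central-difference Hessian; non-positive-definite Hessians (which occur
for a few percent of 6-parameter fits when a parameter is weakly
identified) are repaired by eigenvalue clipping at 1e-6, with a logged
warning.

AIC is `2k + 2·NLL`. Out-of-sample accuracy leaves one block out, fits on
the remainder, runs the latents over the full session (history remains
available), and scores the held-out block as the mean probability assigned
to each observed choice; a hard-classification variant (fraction with
p > 0.5) is available.

Cohort comparison is variational random-effects model selection over the
per-subject Laplace evidences: a Dirichlet posterior over model frequencies
is estimated by iterating responsibilities `r ∝ exp(lme + ψ(α) − ψ(Σα))`,
and exceedance probabilities come from 10^5 Monte-Carlo Dirichlet draws.
This reproduces the quantities used downstream — frequencies,
responsibilities, exceedance probabilities, group labels — without the
hierarchical shrinkage of parameters that a full hierarchical Bayesian
fit would add; it is a deliberate method substitution. Classification is
argmax responsibility, with exact ties broken toward the model with fewer
parameters (logged).

## Behavioral battery

All trial labels are causal (functions of past trials only) and reset at
block boundaries where they depend on the partner's box identity (new
fractals): the observational-consistency label and observational
uncertainty are undefined on the first one and two trials of a block
respectively, while experiential labels (previous reward, win-stay
consistency, magnitude) persist across blocks because the tokens do.
Experiential uncertainty is low when the previous outcome–action–outcome
triplet is win-stay-win, win-shift-loss, loss-stay-loss or loss-shift-win;
magnitude is high when the previous outcome exceeds 25 points.

The choice regression codes `out = ±outcome(t−1)/100` (signed by the
previously chosen token; the /100 scaling is for numerical conditioning
and only rescales the coefficient — a raw-points option exists) and
`pa = ±1` by the goal token implied by the partner's current-trial action.
Split designs zero each regressor outside its uncertainty or magnitude
stratum, so low + high reconstruct the main regressor exactly. The
mixed-effects logistic regression (random intercept and slopes by subject)
is fitted by variational Bayes (statsmodels `BinomialBayesMixedGLM`);
cohorts with near-deterministic choices can quasi-separate and blow up the
variational posterior, which is detected (non-convergence, non-finite
means, or |random effect| > 25) and answered by a flagged fallback to
per-subject ridge-logistic fits summarized across subjects.

Accuracy is choosing the token whose scheduled reward probability exceeds
0.5; learning curves average accuracy at the 8 positions after each
valuable-token flip (block-boundary flips included by default). The
arbitration index is the difference in observational choice propensity
between the trial cell maximally favoring observation (low OL uncertainty,
high EL uncertainty, low magnitude) and the cell maximally favoring
experience (the reverse); it is undefined when either cell is empty.

## Validation suite

The confusion analysis simulates datasets from each model with parameters
drawn from a documented sampler — learning rates U(0.1, 0.9), inverse
temperatures U(1, 10), μ U(0, 0.05) (points scale), ω U(0.1, 0.9),
δ U(−1, 1), baseline biases N(0, 1), spanning shallow-to-steep softmax
regimes — fits all five models to every dataset, and runs the
random-effects comparison per generating condition. At 100 datasets per
model the generating model attains exceedance probability 1.0 in every
condition; at 20 per model the diagonal remains dominant but the fixed
mixture's attribution fluctuates (subjects with ω near 0.5 and shallow
softmax are weakly separable from the dynamic arbitrator at n = 160
trials).

Parameter recovery regenerates data per parameter set, refits, and
correlates truth with recovery across subjects, averaged over repetitions.
Correlations are computed by default in the unconstrained estimation space
(log β, log-odds α): exp-transformed estimates are heavy-tailed on the
natural scale and a single outlier can dominate the cohort correlation; a
natural-scale option exists. The magnitude-boost μ recovers poorly
(r ≈ 0.3) because magnitudes are exogenous and its likelihood contribution
is small — a known identifiability limit, not an optimizer failure.

Posterior predictive checks regenerate each subject's choices from an
assigned model and parameters (one regeneration by default, configurable),
re-run the GLM and curve battery, and compare group-wise data and model
summaries under true and size-preserving shuffled group labels.

## Problem sizes

Default analysis scale: 100-subject cohorts (20 per strategy), 160 trials
each; confusion at 20 (desk) or 100 (full) datasets per model; parameter
recovery at 50 parameter sets; these sizes make every experiment
reproducible in minutes on a single CPU while keeping the cohort-level
comparisons well determined.

## What the synthetic cohorts do and do not show

The generator emulates the task's probabilistic structure and an idealized
informed partner; it does not emulate human lapses (missing responses,
attention drift, session-long non-stationarity in strategy), questionnaire
phenotypes, or the demographic covariates of real cohorts. Passing tests
therefore establishes the internal validity of the models, fitting and
classification machinery — that each strategy is identifiable from the
data it generates under this design — not that human populations decompose
into these five groups. Quantities that depend on human data (group sizes,
absolute accuracies and propensities) are reported for the synthetic
cohorts only.
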