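# Methods

## The task

The play-or-pass Iowa Gambling Task presents one of four decks per trial.
The subject *plays* (draws the deck's next card and receives one net
monetary outcome) or *passes* (nothing happens).  Each deck holds 30 cards;
with four decks the task has 120 trials.  Deck compositions follow the
published per-deck descriptives exactly:

| deck | cards | long-run mean | composition |
|---|---|---|---|
| A | 30 | -$25 | 15 x +$100; losses {-50,-100,-150,-200,-250} x 3 |
| B | 30 | -$25 | 27 x +$100; 3 x -$1150 |
| C | 30 | +$20 | 15 x +$50; 9 x $0; 6 x -$25 |
| D | 30 | +$25 | 27 x +$50; 3 x -$200 |

Decks B, C and D are uniquely pinned by the published cells once every gain
sits at the deck's highest gain and every loss at its highest loss.  Deck
A's fifteen losses are underdetermined (only their sum, count and extreme
are published); we use the graded ladder above, which mirrors the classic
IGT deck-A structure and satisfies every cell.  Card order within a deck
and the interleaved deck-presentation order are seeded permutations; the
"canonical" order is the seed-0 shuffle, so every test and example is
bit-reproducible.  Screen-position counterbalancing does not enter the
model and is not represented.  Trials that time out in the real task are
scored as passes; the simulator exposes a per-trial timeout probability
(default 0, since no timeout rate is published).

## The PP-ORL model

For deck j on trial t the probability of playing is logistic in the value
of playing, with the value of passing fixed at zero:

    P(Y_jt = 1) = 1 / (1 + exp(-V_jt)),
    V_j = EV_j + beta_f * EF_j + beta_b.

`EV_j` (expected outcome value) and `EF_j` (expected win frequency, the
running average outcome sign) update only when the subject plays:

    EV_j <- EV_j + A * (x - EV_j),      A = a_rew if x >= 0 else a_pun
    EF_j <- EF_j + A * (sgn x - EF_j),

while every *other* deck k receives a fictive win-frequency update with the
opposite learning rate toward `-sgn(x)/3` (3 = number of other decks):

    EF_k <- EF_k + A' * (-sgn(x)/3 - EF_k),  A' = a_pun if x >= 0 else a_rew.

Passes leave all state untouched.  Zero outcomes (deck C) take the gain
branch with `sgn(0) = 0`, so they decay EV and EF toward zero; the model
definition's prose ties `a_rew` to strictly positive outcomes but its
equations condition on `x >= 0`, and we follow the equations.

Two numerical conventions matter:

* **Outcome scaling.** Dollars are divided by 100 before entering the
  delta rule (+$100 -> 1.0, -$1150 -> -11.5).  Unscaled EVs of order 10^3
  would saturate the logistic and are inconsistent with response-bias and
  win-frequency weights of order 1-3 on the latent scale; the /100
  convention puts EV, EF*beta_f and beta_b on comparable scales.
* **Initialization.** EV = EF = 0 at trial 1, so the first-trial play
  probability is logistic(beta_b).

The Bernoulli log-mass is computed with a softplus form that is exact on
both tails; probabilities are never clipped.

## Group-level hierarchy

Each of the four person-level parameters gets a linear model on a latent
scale with lifetime-diagnosis indicators (anxiety, depression, substance
use disorder) and sex entered simultaneously:

    mu_i = b0 + b_anx X_anx + b_dep X_dep + b_sud X_sud + b_sex X_sex
    gamma_i = mu_i + z_i * sigma,   z_i ~ Normal(0, 1)   (non-centered)

Learning rates are mapped through the standard normal CDF (probit) into
(0,1); beta_f and beta_b are used as-is.  Indicators enter raw (no
centering), so b0 is the male, no-diagnosis reference mean.  Priors:
Normal(0,1) on every coefficient and every z; Half-Normal(0,2) on the
learning-rate group SDs; Half-Cauchy(0,1) on the beta_f/beta_b group SDs
(read as location 0, scale 1, the standard weakly-informative convention).
Coefficients for the learning rates are reported on the latent probit
scale, not back-transformed.  Interaction terms (comorbidity, diagnosis x
sex) are out of scope.

## Sampling

No external probabilistic-programming backend is used: the package ships a
multinomial No-U-Turn sampler (dual-averaging step size toward a 0.8
acceptance statistic, windowed diagonal mass-matrix adaptation, divergence
flagging at a Hamiltonian error of 1000) over the unconstrained joint
density — group SDs on the log scale with the change-of-variables
Jacobian.  The gradient is analytic: forward-mode tangents of the EV/EF
recursion with respect to the two learning rates are propagated per trial
(the two beta weights enter linearly), then chained through the probit and
the non-centered reparameterization.  The recursion's branches depend only
on data, so the density is smooth; the test suite checks the gradient
against central finite differences (<= 1e-5 relative) and validates the
sampler's moments on closed-form Gaussian targets.

Sampling plans:

* **Full profile** (`SamplerConfig.full_profile()`): 4 chains x 5000
  iterations, 1000 warmup — the plan a full-scale analysis would use.
* **Scaled-down profile** (default): 4 chains x 1000 iterations, 250
  warmup, used on synthetic cohorts of about 40-120 subjects.  On a
  40-subject cohort this yields max split R-hat ~ 1.01, zero divergences,
  and minimum bulk ESS of several hundred in about five minutes on one
  core.
* **Replicate profile** (recovery studies): 1 chain x 300-450 iterations
  with the maximum tree depth capped at 6.  The cap truncates trajectories
  (an efficiency knob that leaves the invariant distribution unchanged)
  and is appropriate where only posterior means and rough intervals are
  needed across many replicate fits.

Convergence is assessed with rank-normalized split R-hat and bulk ESS (via
ArviZ) for every stored quantity — every coefficient, every group SD, and
every person effect — against the 1.1 criterion, plus the sampler's own
divergence count.

## Synthetic cohorts

The generator emulates the study population the pipeline targets:

* **Diagnoses** are drawn jointly from the 8-cell comorbidity table of the
  293-person reference cohort (counts 33/28/23/6/15/38/26 for the seven
  diagnosis combinations and 124 with none), giving marginal lifetime
  prevalences of ~32% anxiety, ~31% depression, ~29% SUD with realistic
  dependence — independent coin flips would understate comorbidity several
  fold.
* **Sex and dyads**: ~74% female; a configurable fraction of subjects
  (default 134/293) belong to opposite-sex parent dyads sharing a
  `dyad_id`.  Within-dyad correlation of person effects is configurable
  and off by default (the reference analysis found r ~ 0.12 on fitted
  values; truths are generated independently unless asked otherwise).
* **Ground-truth coefficients** default to a study-like pattern: probit
  intercepts -1.20 (a_rew) and -1.32 (a_pun), win-frequency weight 3.11,
  response bias 1.22; anxiety +0.15 on punishment learning, female -0.17
  (punishment learning) and -0.30 (response bias), and so on.  The group
  SDs are not published anywhere; 0.45 / 0.45 / 1.2 / 0.65 were fixed once
  as field-typical hierarchical spreads (probit-scale learning-rate SDs
  near 0.5; a beta_f spread matching the width its group-level posterior
  implies) and are not tuned.
* **Behaviour** is simulated agent-by-agent on the shared canonical
  schedule; plays consume the deck's next card.  All three stages
  (covariates, truths, behaviour) are separately seeded, so a cohort is a
  pure function of its spec.

What the generator does **not** emulate: age, race/ethnicity or screening
variables; assortative-mating structure beyond the optional z-correlation;
timeout behaviour (off by default); any deviation from the PP-ORL data
generating process itself.  Passing tests on these cohorts therefore shows
the pipeline is correct and well-calibrated *under the model*, not that
the model is adequate for any particular real dataset — that question is
what the posterior predictive check is for.

## Diagnostics and reporting conventions

* **Posterior predictive checks** re-simulate the whole cohort's behaviour
  from sampled posterior draws and compare observed play proportions per
  group x deck x block (blocks of 10 per-deck presentations by default;
  block indexing is per-deck presentation count, not global trial number)
  with the predictive mean, 50% and 95% central bands.
* **Intervals** are central quantile intervals by default ("95% CI"); a
  highest-density option exists.  The significance flag marks intervals
  excluding zero; the mass-above-zero proportion is reported alongside.
  Report tables round to 2 decimals.
* **Recovery studies** score per-coefficient bias, 95%-interval coverage
  of the truth, and the correlation between true and posterior-mean
  person-level parameters (threshold 0.5 at n = 60 used in tests — an
  artifact-level choice, since "adequate recovery" has no numeric
  definition).
* **Dyad sensitivity** removes one uniformly chosen member per complete
  dyad (seeded) and refits.

## Known limitations

* The sampler is single-threaded and sequential across chains; the full
  profile on hundreds of subjects is an overnight run, not an interactive
  one.
* A deliberately degenerate all-pass cohort identifies person-level
  response biases as negative but *not* the group intercept: the
  heavy-tailed Half-Cauchy group SD lets the posterior push variance into
  sigma instead.  This is a property of the stated priors, not a sampler
  artifact.
* The model variant has no decay/perseveration parameters; the original
  four-deck forced-choice ORL is out of scope.
* Real-data benchmark reproduction requires the original deposited
  dataset, which ships separately from this package; the outcome-scaling
  convention (/100) would need to be reconciled against the deposited
  fitting code before comparing coefficient magnitudes.
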