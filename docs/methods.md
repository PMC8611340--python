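# Methods

`affectdyn` implements a complete simulation-and-analysis world for studying
how goal relevance shapes momentary affective experience: a synthetic version
of a picture-viewing attention experiment, two generative models of
trial-by-trial valence and arousal, per-participant maximum-likelihood
fitting, group-level random-effects Bayesian model selection, recovery
simulations, a lagged relevance-interaction regression, and a
posterior-predictive validation loop.  This note records the models, the
defaults and the design decisions in one place.

## The experimental world

Each synthetic participant views five blocks of 76 affective images and
reports momentary valence and arousal on 0–100 sliders after every fourth
image (19 ratings per block).  Four blocks carry an attention task: a colour
cue renders each upcoming image task-relevant or task-irrelevant, and 160 of
the 304 task images carry a target shape (circle or rectangle, 80 each).
The remaining block is a passive control block (no cues, no targets) placed
first or last, counterbalanced across participants.

Stimuli come from a synthetic 200-image catalog carrying normative valence
and arousal on a 1–7 scale: 100 pleasant (valence > 4.5) and 100 unpleasant
(valence < 3.5) images, the neutral band 3.5–4.5 excluded, and the two
categories matched on mean arousal by rejection sampling (default tolerance
0.1 scale points; up to 1,000 redraws, then an error).  Valence norms are
uniform on [4.6, 6.8] (pleasant) and [1.2, 3.4] (unpleasant), arousal norms
uniform on [3.0, 5.5]: a plausible spread for a normative picture set with
clearly valenced, mid-arousal content.  Model computations use catalog-wide
z-scores of the norms, because the update-rule model has no affine freedom —
stimulus values and ratings must live on a common scale.

Randomized trial assignment respects the original design's balance
constraints exactly: relevant/irrelevant counts equal overall (152/152), per
task block and per temporal position within the four-image windows between
ratings; pleasant/unpleasant equal per block, per task temporal position,
per relevance level and per target condition; no image repeated within a
block, at most two presentations per participant, always in different
blocks.  Marginal balance is achieved constructively (complementary
position-pair families per window), the relevance-by-valence joint count by
bounded rejection.  An independent counting audit re-checks every invariant
after construction.

## Generative models of momentary affect

Both models map the standardized norms `S_1..S_T` of a block onto a latent
affect trajectory, separately per dimension, restarting at each block
boundary, and never conditioning on emitted ratings.

**Exponential decay (ED).**  Affect after stimulus `t` is a discounted sum
of all stimuli so far:

    V_t = w0 + sum_{j<=t} wS[r_j] * gamma[r_j]^(t-j) * S_j,     0 <= gamma <= 1

with `0^0 = 1`, so `gamma = 1` weights stimuli evenly and `gamma = 0` leaves
only the latest stimulus.  In relevance-split (task) fits both the weight
`wS` and the forgetting factor `gamma` applied to stimulus `j` follow that
stimulus's own relevance, while the exponent `t - j` counts all intervening
stimuli regardless of relevance.

**Weighted impact (WI).**  A delta-rule update toward each stimulus:

    V_t = V_{t-1} + beta[r_t] * (S_t - V_{t-1}),   V_0 = x0,   0 <= beta <= 1

equivalently the closed form
`V_t = x0 (1-beta)^t + sum_j beta (1-beta)^(t-j) S_j` (unsplit case).  Every
WI value is a convex combination of `x0` and past stimuli, hence bounded by
their range.  A single shared `x0` is reused at the start of every block of
a fit (one initial-state parameter, not one per block): the initial state is
already weakly identified from 19–76 ratings, and per-block initial states
would add three parameters that decay away within a few trials.

Ratings are the latent trajectory at rating trials plus iid Gaussian noise.
The slider rendering (`50 + 20z`, clipped to [0, 100]) is bookkeeping for
the exclusion rules; modelling happens on the standardized scale.  Observed
ratings are standardized per participant with the sample sd, pooling all of
a participant's ratings in a dimension; zero-variance participant-dimensions
are flagged for exclusion rather than divided by zero.  Participants who
leave a slider unmoved (exactly at 50) on more than 80% of ratings on either
scale are excluded entirely; all-unmoved control-block arousal excludes that
participant from control-arousal fits only.

## Fitting and model comparison

Each participant-dimension is fitted by maximum likelihood under the normal
observation model, with bounded L-BFGS-B from 10 (default) uniformly drawn
start points inside the box `beta, gamma in [0,1]`, `w0, x0 in [-3,3]`,
`wS in [-5,5]`; ties between restarts break first-found, and runs are
bit-reproducible given the seed.  The noise sd `sigma` is profiled
analytically at each candidate — its conditional MLE is the residual rms,
clipped to `[1e-3, 5]` — which removes one search dimension without changing
the optimum; `sigma` still counts as a free parameter in the AIC
(`2k − 2 lnL`; control fits: WI k=3, ED k=4; task fits: WI k=4, ED k=6).

Group-level selection treats `−AIC/2` as each participant's log model
evidence and estimates the Dirichlet posterior over population model
frequencies by variational Bayes (uniform prior `alpha0 = 1`, tolerance 1e-6
on alpha, max 500 iterations).  Exceedance probabilities use the regularized
incomplete-beta closed form for two models and seeded Dirichlet Monte Carlo
(1e6 draws) otherwise.  The Bayes omnibus risk compares the variational free
energy of the random-effects model with the equal-frequency null
(`F0 = sum_n log mean_k exp(lme_nk)`); protected exceedance probabilities
are `pxp = xp (1 − bor) + bor/K`.  Note the BOR approaches 1 only slowly as
evidence differences vanish at finite N (≈0.8 at N = 25); the `pxp` still
collapses to 1/K exactly in that limit.

## Recovery simulations

Model recovery draws participant-level parameters from broad uniform priors
(`beta, gamma ~ U(0.1, 0.9)`, `w0 ~ U(−0.5, 0.5)`, `wS ~ U(0.1, 1)`,
`x0 ~ U(−1, 1)`, noise sd `~ U(0.3, 1)` — spanning the plausible fitted
range on standardized data), simulates valence and arousal ratings from one
model, fits both models to every participant, and selects the dataset-level
winner by protected exceedance probability on the summed
(valence + arousal) evidence; ties within 1e-6 count against recovery.  One
schedule is generated per run and reused across datasets — schedules are
exchangeable under the balance constraints, so resampling parameters, noise
and ratings is the informative part.  Parameter recovery refits the
generating model and reports per-parameter Pearson correlation and mean
bias.  Update weights recover well from 76 task ratings (r ≈ 0.95+ at noise
sd 0.5); the initial state `x0` recovers poorly by construction, since its
influence decays within a few trials of each block.

## Lagged regression and post-hoc machinery

Each rating has exactly four preceding images, so the descriptive analysis
regresses participant-standardized ratings on the standardized norms of
those four images (lag 1 = most recent; lags never cross a rating
boundary), valence on valence norms and arousal on arousal norms only.  The
task-block model appends `S_lagk × relevance_lagk` interaction columns and
deliberately omits relevance main effects: the question is whether relevance
modulates the affective impact of a stimulus, not whether a cue shifts
ratings by itself.  Group-level fixed effects come from a linear mixed model
with participant random intercepts and slopes on all predictors (REML,
full random-effects covariance), falling back — flagged — to the two-stage
summary-statistics estimator (per-participant OLS, then across-participant
mean and se with t-based p-values) when the mixed fit fails; in this
balanced design the two agree to a few hundredths.  Pairwise coefficient
comparisons use Wald z-tests with the full coefficient covariance;
multiplicity is controlled by Holm's step-down procedure.  The a-priori
power utility inverts the exact noncentral-t power function of the paired
t-test (dz = 0.5, power 0.95, two-sided alpha 0.05 gives n = 54).

## Posterior-predictive validation

Given per-participant WI parameters and noise sds (typically the MLEs), the
validation loop simulates full datasets on the *same* schedules, re-runs the
lagged interaction regression on each (two-stage estimator, for the
100-regression loop), and checks whether each reference coefficient lies
inside the central 95% of its simulated distribution.  Reusing schedules
rather than regenerating them matches the reference analysis and isolates
parameter- and noise-driven variability.

## What the synthetic world does and does not show

The generator reproduces the design arithmetic, the balance constraints,
the rating cadence, the two generative processes and the slider exclusion
rules.  It does not emulate real raters: no drift, no anchoring or slider
inertia, no heavy-tailed or autocorrelated noise, no cross-dimension
coupling between valence and arousal, and normative norms are treated as
exact stimulus properties.  Passing recovery and calibration tests
therefore shows that the *pipeline* is correct and well-conditioned at the
study's scale — not that the models are true of human affect.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale versions of the simulation
studies: model recovery at 10 datasets per model × 20 participants (task)
and 20 × 20 (control), parameter recovery at 50 participants, validation at
30 simulations; the same functions run the full scale (100 datasets per
model, 83 participants) by default arguments.  Optimizer tolerances are
ftol 1e-10 / gtol 1e-8; BMS tolerance 1e-6; trajectory equivalence is exact
to 1e-10; Monte Carlo exceedance agrees with the closed form to 0.002 at
1e6 draws.  Degenerate inputs fail loudly: impossible arousal matching and
unsatisfiable schedule constraints raise after 1,000 attempts, zero-variance
standardization flags instead of dividing, and the closed-form WI rejects
relevance-split parameters (the split model has no single-rate geometric
form).
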