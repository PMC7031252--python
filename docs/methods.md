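# Methods

## Task generative process

One session is 300 trials: two 150-trial hazard stretches (stable,
H = 0.025; volatile, H = 0.125) in random order, cut into 4 blocks of 75.
Rather than drawing change-points Bernoulli-per-trial, the generator
places the configured *count* of change-points (4 stable / 19 volatile)
uniformly without replacement over trials 2..150 of each stretch, so the
empirical hazard equals the nominal one exactly for every seed; the
nominal hazard is what the learner assumes. No minimum spacing is
enforced, so adjacent change-points can occur. The generative mean is
uniform over the 360 integer circle positions at the session start and at
each change-point; block breaks do not reset it. Outcomes are
`wrap(round(mean + N(0, 12²)))`, giving integer positions in [1, 360].

Angles use the convention: positions in [1, 360]; signed differences in
(−180, 180] with +180 at the antipode; distance is the absolute signed
difference. Internally continuous angles are kept unrounded (beliefs,
bucket dynamics); only task-visible positions are integers.

The bucket half-width (default 25°) is a free parameter of the simulated
task — it is not derivable from the session statistics — so every
quantity that depends on hit rates (points, the Hit regressor's base rate,
hit-related effects) is conditional on this choice.

## Reduced Bayesian learner

Per trial, with outcome `X`, belief `B`, generative variance
`s = σ_N² = 144`:

    δ  = signed_arc(X, B)
    σ² = s + (1 − ν) s / ν                 (ν floored at 1e-6)
    Ω  = (H/360) / (H/360 + N(δ; 0, σ²)(1 − H))
    α  = Ω + (1 − Ω) τ,        τ = 1 − ν
    B' = wrap(B + α δ)
    τ' = [Ω s + (1 − Ω) τ s + Ω(1 − Ω)(δ(1 − τ))²] / (same + s)

The relative-uncertainty ratio τ' resets to 1/2 after a certain
change-point and decays as τ/(1+τ) in a quiet world, so model confidence
ν = 1 − τ grows as evidence accumulates; writing the update on τ rather
than ν is what makes the three equations mutually consistent (the ratio
measures uncertainty, while ν in the variance and learning-rate equations
is confidence). `RU = (1 − Ω)τ` is the relative-uncertainty regressor;
note the exact identity `α = Ω + RU`, which the action evidence model
mirrors with its `|δ|×CPP` and `|δ|×RU` interaction terms.

Numerical choices: the change-point likelihood uses the plain unwrapped
normal density at the signed error (no wrapped-normal correction; errors
are ≪ 180° whenever the belief is informative); the belief is initialised
at the first outcome with τ = 1, so trial 1 contributes no prediction
error and is excluded from every regression; the trace is deterministic
given outcomes and hazards.

## Synthetic cohort

The cohort model is a generative inverse of the analyses: no claim is
made that humans produce behaviour this way, only that the regressions
have a known ground truth.

Dimension scores (AD, CIT, SW) are multivariate standard normal with
pairwise correlations 0.52 / 0.43 / 0.34 — chosen once inside the
moderate band real factor scores occupy. Covariates: standardized age and
IQ, gender ~ Bernoulli(0.42) (cosmetic realism only).

Agent parameters are a deterministic linear map from the scores
(`param = default + Σ effect × score`) plus independent subject-level
jitter (SD 3 confidence units on the confidence intercept, 0.05 on the
coupling). The jitter represents individual variation that no three
traits explain; it also keeps the mixed models' random-effect variances
off the REML boundary, where numerical optimisers misbehave.

Per trial the agent reports confidence built from the previous trial's
normative evidence (z-scored within session),

    c = intercept − w_cpp z(CPP) − w_ru z(RU) + w_hit Hit − w_pe z(|δ|) + noise,

clipped to [1, 100], and moves its bucket by

    m = α |pe| (1 + coupling · (−z(c))) + sw_pe_gain |δ| + noise,   m ≥ 0,

along the sign of `pe`, its *own* prediction error (outcome minus own
bucket). Using the agent's own error for the tracking term makes bucket
error mean-reverting (with the learner's δ it would be a random walk away
from the belief), and reduces exactly to the learner's bucket when all
noise and modulation are zero. The social-withdrawal gain multiplies the
learner's |δ| instead, so the extra movement is proportional to the exact
regressor the action evidence model tests; a gain on the agent's own
error is absorbed into the tracking dynamics and is nearly invisible to
that design (verified by simulation). Confidence is causally upstream of
the same trial's action — one admissible mechanism for the coupling.

Defaults: intercept 60, w_cpp = w_ru = 6, w_hit = 8, w_pe = 4 (confidence
units per predictor SD), coupling 0.6, confidence noise SD 8, action
noise SD 4°. Effect map (+1 SD of the dimension): CIT +6.74 on the
intercept, −1.5 on w_cpp and w_ru, −2.5 on w_hit, −0.10 on coupling;
AD −3.42 on the intercept; SW +0.15 on sw_pe_gain. The confidence-level
shifts reuse the magnitudes reported for this design at n = 437; the
remaining magnitudes were calibrated once so that the simulated
moderation t-statistics at 437 subjects land in the same significance
tiers as the reference analysis (the SW gain needs ≈0.15 because roughly
two-thirds of it is absorbed by the closed-loop bucket dynamics). These
are generator configuration, not empirical claims.

What the generator does *not* emulate: response-device and motor noise
structure, attention lapses, confidence anchoring/drift, learning of the
hazard itself, participant-level data-quality failures. Passing recovery
tests therefore show that the analysis pipeline is correct and
well-calibrated for this model family — not that real data satisfy it.

## Derived measures and exclusions

Per subject: signed update = signed arc from bucket_t to bucket_{t+1};
action = |signed update|; PE = signed arc from bucket to outcome;
LRh = signed update / signed PE (undefined at PE = 0). Confidence is
paired as c_{t+1} against trial-t evidence, matching the timing of the
generative model.

Exclusions: PE = 0 trials, and trials with LRh above the pooled dataset's
99th percentile (computed after removing PE = 0 trials; one-sided upper
cut). The threshold is a quantile of each dataset, not a constant —
reference datasets report values like 7.75; the synthetic cohort's is
typically ~4. Updates across block breaks are retained by default
(flagged, excludable by option). Exclusion is idempotent.

## Regression suite

All models are linear mixed models fit by REML (statsmodels MixedLM),
grouped by subject:

* coupling: `action ~ z(confidence) + covariates [+ moderators +
  moderator × z(confidence)]`, random intercept and random confidence
  slope (moderator × slope random terms are not estimable and stay
  fixed-only);
* level: `confidence | action ~ covariates [+ moderators]`, random
  intercept;
* evidence on action: `action ~ |δ| + |δ|:CPP + |δ|:RU + |δ|:Hit + ...`,
  raw scales, random intercept; evidence on confidence: the same
  variables as main effects, z-scored within subject (Hit kept 0/1,
  confidence on its raw 1–100 scale), random intercept.

Covariates: age and IQ z-scored across subjects, gender 0/1. Moderators
are z-scored across subjects. Two moderator regimes mirror standard
practice: each questionnaire score in its own model (Bonferroni m = 9) or
the three dimensions jointly (m = 3); with a single moderator the two
regimes are the same fit.

Inference: Wald 95% CIs on the classical SEs; Bonferroni-adjusted
p-values on moderator terms; subject-clustered sandwich SEs computed from
the fitted marginal covariance (V_g = Z_g G Z_gᵀ + σ²I, Woodbury inverse,
G/(G−1) correction) reported alongside, with robust p-values. White's
test (auxiliary regression of squared residuals) screens for
heteroskedasticity. Optimisation: lbfgs first, falling back to powell
then bfgs whenever a candidate fit returns non-finite fixed-effect SEs
(lbfgs degenerates when a variance component sits exactly on the
boundary); non-convergence is flagged on the result, never raised.
Moderation size is summarised as `100 · β_interaction / |β_main|`
(percent change of the main effect per moderator SD).

## Factor scoring

Scores = column-standardized items (sample SD) × weight matrix, joined on
item labels; 209 items from nine instruments (AUDIT 10, AES 18, SDS 20,
EAT-26 26, BIS 30, OCI-R 18, STAI-trait 20, SSMS 43, LSAS 24). The true
published weights are external configuration; the repository ships only
clearly-labelled synthetic fixtures whose induced factor correlations at
n = 2,000 fall in the 0.34–0.52 band. Standardizing items before
weighting is the conventional factor-score procedure and is an assumption
here; scoring is invariant to item order and scale.

## Problem sizes and calibration checks

Recovery is verified at the study scale — 437 subjects × 300 trials — for
20 replicates (sign correctness of all four configured moderations in
≥95%), and null calibration on 8 zero-effect cohorts at the same scale
(robust Bonferroni-corrected false-positive rate ≤ nominal α with
three-sigma Monte-Carlo slack); unit tests use 30–80 subjects. The null
check uses the cluster-robust p-values because the generator's
subject-level coupling jitter is exactly the kind of unmodelled slope
heterogeneity that model-based SEs understate.

## Known limitations

* The bucket half-width is unconstrained by the session statistics; hit
  base rates (~0.65 at the default 25°) are a modelling choice.
* Confidence clipping at 100 attenuates large injected confidence-level
  effects (a +6.74 shift is recovered as ≈+5 at the default intercept);
  sign and tier recovery are unaffected.
* The agent's evidence weights act on within-session z-scores, so
  absolute regression magnitudes depend on session variability; only
  directions and relative tiers are calibrated.
* Evidence models assume random intercepts only; true per-subject
  evidence-weight variability appears in the robust SEs, not the model.
* No Bayesian estimation, no hazard/noise fitting to behaviour, no figure
  reproduction.
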