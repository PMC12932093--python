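# Methods

## The paradigm and its outcome logic

The task is a sequence of 13 one-shot moral dilemmas with a binary yes/no
choice each. Eight dilemmas frame the cost–benefit (CBR) option as the
action under consideration and five frame the rule option as the action,
so the strategy a response expresses (CBR vs. rules) is decoupled from
the behaviour it constitutes (action vs. omission). Outcome valence is
deterministic given the condition: the CBR option always yields an
overall good outcome in CBR Success and an overall bad one in Rule
Success, and vice versa for the rule option. The participant's moral
evaluation of the outcome, a −100…100 rating divided by 100
(MJ ∈ [−1, 1]), is the learning signal. The `paradigm` module encodes
exactly these mappings and validates any trial sequence against them.

The default dilemma list is fixed-order (8 CBR-framed dilemmas followed
by 5 rule-framed). Trial-order randomization is left to the caller's
seeded shuffle; a fixed order keeps simulations and fits reproducible and
none of the inferential machinery depends on the order of framings.

## Models

All six models emit a Bernoulli probability for each trial's yes/no
response; the latent "chosen mechanism" is identified with the observed
chosen option, derived deterministically from (framing, choice), which is
the only observable proxy for it.

- **MF-M / MF-B** — Q-learning over two units (CBR/rules, or
  action/omission). Both Q-values start at 0, the neutral midpoint of the
  evaluation scale, which makes the first-trial choice probability 0.5.
  After each trial the chosen unit's value moves toward the evaluation:
  Q ← Q − α·(Q − MJ), α ∈ [0, 1]. The unchosen unit is untouched. With
  MJ ∈ [−1, 1] the Q-values stay in [−1, 1] forever (contraction).
- **MB-M / MB-B** — independent Beta–Bernoulli learners per unit, prior
  Beta(a₀, a₀). The good count increments when the chosen unit's MJ > 0,
  the bad count when MJ < 0; an MJ of exactly 0 updates nothing (neither
  sign indicator fires). Choice probabilities are a softmax with inverse
  temperature τ over the two Beta *posterior means* — a deterministic
  plug-in, required for the likelihood to be a function of the parameters
  alone so that the evidence integral is well defined without sampling
  latent draws.
- **C-M / C-B** — constant rate θ of choosing the CBR option (or the
  action); the no-learning baselines.

τ is shared in name across MF and MB models but operates on different
scales (Q ∈ [−1, 1] differences vs. posterior-mean differences in
[−1, 1] but typically much smaller); no rescaling is applied — the
models are compared as specified, and the τ prior covers both regimes.

Useful degeneracies, used as test oracles: MF with α = 0, MB with τ = 0
and C with θ = 0.5 all reduce to a fair coin, assigning n·ln(½) to any
n-trial sequence.

## Priors

| parameter | prior | why |
|---|---|---|
| τ (inverse temperature) | lognormal(0, 1.4) | 90% of mass on [0.1, 10], spanning near-random to near-deterministic choice |
| α (learning rate) | Uniform[0, 1] | rates outside [0, 1] are not meaningful updates |
| a₀ (prior pseudo-count) | Gamma(2.57, rate 0.54) | 90% of mass on [1, 10]: between 1 and 10 previously seen outcomes of each valence |
| θ (constant rate) | Uniform[0, 1] | uninformative baseline |

## Evidence by quadrature

Each model has 1–2 free parameters, so the marginal likelihood is
computed by deterministic Gauss–Legendre quadrature rather than MCMC plus
bridge sampling: substituting u = F(param) (the prior CDF) turns
∫ L·π dparam into ∫ L(F⁻¹(u)) du on the unit interval, integrated with
201 nodes per dimension (config-exposed). Uniform parameters keep their
natural [0, 1] scale, which makes the constant-model evidence — the Beta
function B(k+1, n−k+1) — exact to machine precision (a closed-form test
oracle). Unbounded parameters use nodes on the 0.0005–0.9995 prior
quantile range; the neglected tail mass bounds the truncation error at
0.001 of the evidence (< ~0.001 nats), far below the reported
grid-refinement error estimate (the absolute change in log evidence when
the node count is doubled). Accumulation is in log space throughout.

An independent cross-check — a seeded Monte-Carlo estimator averaging
the likelihood over 2×10⁵ prior draws — agrees with the quadrature to
well under 0.05 nats across models and synthetic participants; the
acceptance script recomputes this margin on every run.

Posterior parameter means and standard deviations come from the same
grid (normalized posterior weights), with no separate sampler. Fits are
per participant; no hierarchical pooling is attempted.

## Cohort-level inference

Random-effects Bayesian model selection treats each participant's model
identity as drawn from unknown population frequencies f with a
Dirichlet(α₀) prior, α₀ = 1 per model. The standard variational
fixed-point (responsibilities u_nk ∝ exp(lml_nk + ψ(α_k) − ψ(Σα));
α = α₀ + Σₙuₙ) is iterated to a 1e−8 change in α. Expected frequencies
are α/Σα; exceedance probabilities are Monte-Carlo estimates over
100,000 seeded Dirichlet draws. Exceedance (not protected exceedance) is
reported. For family-level inference the per-model prior counts are
1/|family|, giving each family equal prior mass; family frequencies and
exceedance are computed from summed member frequencies/draws.

The inclusion Bayes factor for a family compares Σ of the family's
marginal likelihoods against Σ of the rest, divided by the prior odds
under a uniform prior *over models* (2:4 for the two-model metacognitive
family). A uniform prior over families is a defensible alternative; the
choice is exposed through the family argument and the uniform-over-models
convention is the default. The recentred scale is log₁₀(BF) − 1, so 0
marks BF = 10 ("strong evidence").

## Synthetic cohorts

The generator simulates the paradigm exactly: model state → choice
probability through the dilemma's framing → sampled choice → derived
strategy/behaviour → deterministic valence → rating → state update.
Ratings have the valence-congruent sign with probability 1 − ε (default
ε = 0: the paradigm's outcomes are deterministic and the materials were
calibrated so good outcomes are rated positive and bad ones negative),
and integer magnitudes 100×Uniform(0.3, 1.0) — the real rating
distribution's shape is unknown beyond its sign, and a magnitude bounded
away from zero keeps the model-free learning signal informative. Ratings
are never exactly 0, so the beta-Bernoulli sign indicators always fire on
simulated data; real data with zero ratings are handled by the models
(no MB update, MF update toward 0).

What the synthetic checks therefore establish: the estimation and
selection machinery is correct and well calibrated *under the generative
assumptions of the six models*. What they do not establish: that real
participants' ratings follow the assumed magnitude distribution, that
real choice sequences are stationary in the models' sense, or the exact
expected-frequency values of any particular empirical cohort.

## Model recovery

The recovery harness simulates cohorts from each of the six models
(parameters drawn from the fitting priors, participants split evenly
between the two conditions since either could have been used in the
original simulations), refits all six models, and tabulates argmax
evidence; exact ties count as non-recovery (conservative). At the
paradigm's own scale (13 trials, 60 participants per generating model)
the *family-level* confusion matrix is reliably diagonal-modal; the
default problem size for this study is 60×6 participants at 201-node
grids, about 3–4 minutes on one CPU.

A known identifiability limit, visible in the model-level confusion at
both 13 and 200 trials: with deterministic outcomes, strategy learning
saturates within a few trials, after which MB-M and MF-M produce nearly
identical likelihoods; their confusions are mutual and stay within the
metacognitive family. Behaviour-space learners remain better separated
because the framing mix keeps their learning signal bivalent. Per-model
recovery rates should therefore be read per family for the strategy
learners.

## Learning-curve statistic

The headline behavioural trend — participants drift toward the
reinforced option — is summarized by a pooled logistic regression of the
binary CBR-choice indicator on ln(trial), per condition (raw trial is an
option). This deliberately simplifies the original mixed-effects
specification: random effects and external appropriateness-rating
covariates are routine additions that require data not shipped here, and
only the direction and strength of the trend are needed for validation.
A complete-separation fit is flagged with an infinite-slope sentinel
rather than raised.

Model-based strategy-learning cohorts (a₀ = 2, τ = 5, a mid-prior,
clearly-learning regime chosen once) give a positive slope in CBR Success
and a negative one in Rule Success, matching the direction expected from
the paradigm's reinforcement structure.

## Known limitations

- No hybrid or mixture models, and no per-dilemma (situation-specific)
  values: the models keep one value per strategy/behaviour across all
  dilemmas, the single-value reading of the paradigm.
- The evidence integrals truncate the τ and a₀ priors at their
  0.05%/99.95% quantiles (error bounded as above).
- Importing real study data requires a column-mapping adapter
  (`read_dataset` defines the dialect; external layouts differ and no
  adapter is shipped).
- Exceedance probabilities are Monte-Carlo estimates; with 100,000 draws
  their standard error is ≤ 0.0016.
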