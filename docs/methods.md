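# Methods

## The task

The four-choice probabilistic serial reaction time (SRT) task presents a
stimulus in one of four locations; the participant presses the matching
key. The location on trial *t* is a second-order conditional (SOC)
function of the locations on trials *t−1* and *t−2*: two fixed SOC
sequences,

    A: 1-2-1-4-3-2-4-1-3-4-2-3 (cycled)
    B: 1-3-2-3-4-1-2-4-3-1-4-2 (cycled)

each map all 12 ordered pairs of distinct locations to a successor. On
every trial the continuation of the current pair is taken from the
high-probability sequence with probability `p_high = 0.85` and from the
low-probability sequence otherwise. After 960 trials the roles reverse
(sequence B becomes the 85% generator) for a second 960-trial session.
Faster responses to high-probability transitions index implicit learning
of this structure; the reversal probes relearning under volatility.

`cathgf.task` generates exactly this stream. Each session's first two
stimuli seed the SOC context with a uniformly random ordered pair from the
high-probability sequence's 12 pairs (the original task description does
not specify the initial trials; a random valid pair avoids biasing any
location), and the context is re-seeded after the between-session break.
Neither printed sequence repeats a location, so the generated stream never
contains an immediate repetition.

## The learner: a categorical state-transition HGF

Beliefs about all 16 ordered transitions i→j between the four locations
are tracked by independent Gaussian beliefs over transition log-odds
(mean μ, precision π), one continuous node per transition, each the parent
of a binary occurrence node. A single log-volatility parameter ω, shared
by all 16 nodes, encodes how quickly the environment is assumed to drift.

Per trial, every node first makes a volatility prediction

    μ̂ = μ,    π̂ = 1 / (1/π + exp(ω)),

i.e. the log-odds is assumed to have diffused with variance Ω = exp(ω)
since the previous trial. The predicted transition matrix is obtained by
passing the μ̂ of each row (from-location) through the logistic S(·) and
normalising the row. When a transition from location *i* is observed, the
four binary children of row *i* receive outcomes (1 for the observed
transition, 0 for its siblings) and their parents update as standard
binary-child continuous parents:

    b̂ = S(μ̂),   δ = outcome − b̂,
    π = π̂ + b̂(1 − b̂),   μ = μ̂ + δ/π.

Updates are therefore precision-weighted: large when the prediction error
is large and the belief imprecise. Nodes in inactive rows adopt their
predicted state as the posterior — time passes for unobserved transitions
too, which is what makes ω's forgetting effect global. Initial beliefs are
fixed at μ₀ = 0, π₀ = 1 (a uniform 0.25 transition matrix) and are not
estimated; ω is the only free perceptual parameter.

Trial 1 of a session scores no transition: the prediction is recorded but
no node updates. Beliefs carry across the between-session break (the
volatility prediction still runs), but the break itself is not scored as a
transition.

### Trial regressors

For the observed transition i→j with pre-update predicted state (μ̂, π̂)
and predicted row **p**:

* surprise ℑ = −log p(j | i) (Shannon surprise, nats);
* expected uncertainty U_e = S(μ̂)(1 − S(μ̂)) / π̂;
* unexpected uncertainty U_u = U_e · exp(ω).

The precision entering U_e is evaluated as the *predicted* precision π̂ of
the current trial — the quantity available before the outcome — rather
than the previous trial's posterior; the two differ only by one volatility
step. Session-first trials have no transition: surprise is set to ln 4
(the uniform four-way prediction, which is also the model's genuine first
prediction) and both uncertainties to 0, so the regressor table has no
gaps. The participant-level summary `participant_mean_pe` averages |δ|
per node over that node's update trials and then across the 16 nodes;
the absolute value is used because signed binary prediction errors average
toward zero by construction.

## Response model

Log reaction times (natural log, RT in ms) are modelled as

    μ_RT = β₀ + β₁·ℑ + β₂·U_e + β₃·U_u + β₄·post_error + β₅·post_reversal
    log RT ~ N(μ_RT, σ),

where post_error flags trials following an incorrect or missed response
and post_reversal flags the second session. β₀ ≈ 5.8 corresponds to
~340 ms. Regressors enter raw (a z-scoring switch exists), and RTs of
error trials are included by default (their successors carry the
post-error regressor either way); both choices are configurable.

RT preprocessing follows the usual SRT rules: responses < 200 ms are
anticipations; per participant, responses above mean + 2 SD of the
remaining RTs are lapses. The slow rule is one-sided since the fast tail
is already floored at 200 ms. Missing RTs are always excluded.

## Inference

The joint model has 8 free parameters (ω, β₀–β₅, σ). For every proposed ω
the filter is re-run over the participant's stimulus stream (a compiled
scalar-loop kernel, `cathgf._fast`, numerically identical to the readable
implementation to ~1e-15), and the Gaussian likelihood of the included
log RTs is evaluated. Default priors are weakly informative —
ω ~ N(−3, 2), β₀ ~ N(6, 2), β₁–β₅ ~ N(0, 1), σ ~ HalfNormal(0.5) — and
fully overridable.

Sampling uses the affine-invariant ensemble sampler (emcee) with a mixture
of differential-evolution moves (80% DEMove, 20% DESnookerMove). Four
independent ensembles play the role of four chains. "Samples per chain"
counts warmup + retained draws: the default 2,000 retains 1,000 draws per
chain, taken as the flattened, thinned post-warmup walker states (40
walkers, thinning 20, warmup twice the sampling phase). DE moves matter
here: at fixed ω the U_e and U_u columns are exactly proportional, so β₂
and β₃ are identified only jointly (plus priors), leaving a long posterior
ridge that stretch moves traverse slowly.

Walker initialisation draws ω and σ near their priors but starts the βs at
the ordinary-least-squares solution of the design at the drawn ω, with
multiplicative and additive jitter; a pure prior-draw initialisation is
available (`init="prior"`). This puts every walker near the posterior
ridge and makes warmup reliable.

Diagnostics: split Gelman–Rubin r̂ per parameter (own implementation,
cross-checked against ArviZ's split method), bulk ESS via ArviZ, mean
ensemble acceptance fraction. A fit warns (never fails) when any r̂
exceeds 1.01; the CLI `fit` command turns that warning into exit code 3.
Ensemble MCMC has no divergence concept; the acceptance fraction is the
analogous health signal. Credible intervals are 94% equal-tailed.
Likelihood evaluations are pure: the filter restarts from its fixed
initial beliefs on every call, so identical (data, θ) always give the same
value.

## Synthetic agents and parameter recovery

`simulate_agent` composes the forward model: stimuli from the task
generator, correctness as exogenous independent Bernoulli errors (default
rate 0.08, matching the ~0.92 accuracy typical of this task — the learner
does not model choice errors), and log RTs drawn from the response model
along the agent's own belief trajectory. Missed responses are not
simulated. Default simulating values are ω = −4 with the group-mean
response weights (β₀ = 5.83, β₁ = 0.05, β₂ = −0.02, β₃ = −0.15,
β₄ = 0.10, β₅ = −0.01) and σ = 0.2.

What the simulator deliberately does not emulate: attentional lapses and
anticipations (there are no RT outliers beyond the model's own Gaussian
tail), missed responses, accuracy that depends on beliefs, and any motor
or sequence-specific effects outside the six regressors. Passing tests
therefore show that the machinery is correct and well-calibrated on data
that obey the model — not that the model captures every feature of real
behaviour.

`recovery_study` draws true parameters uniformly over prior-plausible
spans (ω ∈ [−6, −2]; β and σ over ranges consistent with the fitting
priors), simulates each agent at the full task size (2 × 960 trials), fits
it, and reports per-parameter correlation(true, posterior mean), bias,
RMSE and credible-interval coverage. Two design points matter:

* Truths are varied across the whole parameter space rather than pinned at
  the group means. With β₁–β₃ fixed near zero the belief regressors carry
  almost no signal and ω is close to unidentifiable by construction;
  moreover interval coverage is only expected to be near-nominal when
  truths vary compatibly with the priors.
* Recovery fits disable the RT outlier exclusions (`rt_exclusions=False`):
  simulated data contain no lapses, so the mean + 2 SD rule would simply
  truncate the top of a valid Gaussian sample and bias σ low. Real-data
  fits keep the exclusions on by default.

Recovery fits use a lighter sampler setting (2 chains, 1,000 samples per
chain, 20 walkers, thinning 12) than single-participant fits; the study's
score is aggregate correlation/coverage, not per-agent diagnostics.

## Numerical choices

* Logistic computed in a branch-free stable form; exp(ω) clamped at 1e12;
  precisions floored at 1e-12.
* Overflowing likelihood at extreme proposals returns −∞ (rejection)
  rather than raising.
* The straight-through trial loop is O(T) with a 4×4 state; the compiled
  kernel evaluates a 1,920-trial stream in ~0.2 ms, which is what makes
  full-size MCMC (≈3 × 10⁵ likelihood calls) run in about a minute.
* Problem sizes used by the shipped checks: single-participant fits at the
  full 2 × 960 trials with 4 chains × 2,000 samples; recovery at 10 agents,
  full-size data, lighter sampling. These match the study's conditions
  while keeping a complete run of the workflow in the minutes range.

## Known limitations

* β₂ and β₃ are individually weakly identified (exact collinearity of
  U_e and U_u at fixed ω); their joint combination is what the data
  constrain. Expect wide, correlated posteriors for these two.
* σ estimated after lapse exclusion on real data is an estimate of the
  post-exclusion residual SD, slightly below the raw SD by construction.
* The split r̂ of a well-mixed run fluctuates a few thousandths above 1;
  values up to ~1.01 are sampling noise at these ESS levels, not evidence
  of non-convergence.
* No volatility parents above the transition nodes (a 2-level filter with
  shared ω), no drift, no value coupling between transitions — matching
  the model whose behaviour this package reproduces.
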