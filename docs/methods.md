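# Methods

## The experiment being emulated

A participant stands in a virtual bar while one character (the
perpetrator, P) verbally and then physically attacks another (the victim,
V). Starting 4 s after the confrontation begins, and every 10 s
thereafter, an adaptive agent triggers one of three character actions —
the victim looks at the participant (`VictimLookAt`), the perpetrator
looks at the participant (`PerpLookAt`), or one of three virtual
bystanders says an encouraging line (`BystandersUtter`). A 130 s
confrontation therefore holds 13 action slots. During each 10 s window
the participant may intervene *verbally* (address any character) or
*physically* (approach, gesture, step between them); staying within 0.5 m
of the arguing pair counts as a physical intervention automatically.

The package replaces the human participant with a synthetic one and the
CAVE-style hardware with a scalar distance abstraction, keeping the rest
of the design: the agent, the cohort structure, the logged variables, and
the statistical analysis.

## Reinforcement learning layer

State is the proxemic band of the participant relative to the arguing
pair: `Intervention` (< 0.5 m), `Active` (0.5–1 m), `Passive` (≥ 1 m).
The printed band definitions use strict inequalities that leave the two
boundary distances unassigned; we use lower-inclusive half-open bands, a
measure-zero choice. Action is one of the three character actions. Reward
per window is +1 per intervention type present (maximum 2) and −0.1 when
the participant does nothing — the small penalty pushes exploration.

Learning is tabular Watkins' Q(λ) with accumulating eligibility traces:

    δ_t = r_t + γ max_a Q(s_{t+1}, a) − Q(s_t, a_t)      (terminal: δ_t = r_t − Q)
    e(s_t, a_t) += 1
    Q(s, a)     += α δ_t e(s, a)        for every pair
    e(s, a)      = γ λ e(s, a)  if the next action is greedy, else 0

with α = 0.2, γ = 1.0 (all interventions count equally regardless of
when they occur), λ = 0.2. Actions are ε-greedy: with probability ε the
action is uniform random (this is what `proprandom` counts); otherwise the
argmax of Q in the current state, ties broken uniformly. Whether a chosen
action cuts the traces is decided by whether it is greedy with respect to
the current Q table, not by which branch sampled it. Accumulating (rather
than replacing) traces and the no-bootstrap terminal convention are our
choices; the terminal slot is the 13th.

A study runs three cohorts of 15 participants with ε = 1 (RLLevel
`None`), 0.66 (`Medium`) and 0.33 (`High`). Cohort 1 starts from Q ≡ 0;
each later cohort starts from the element-wise mean of the previous
cohort's 15 final tables, so knowledge accumulates across cohorts. Every
session draws from its own child generator spawned from the master seed;
a study is bit-reproducible from that one integer.

## Synthetic participants

Each participant responds in a window with probability

    P(y = 1 | action) = inv_logit(u + b_vl·vl + b_pl·pl + b_bu·bu)

with subject effect u ~ Normal(0, σ_u), σ_u = 1 by default, and action
weights on the unit simplex, default (0.59, 0.29, 0.12) — victim gaze the
strongest cue, bystander utterance the weakest. These defaults make
"recover the weight ordering from simulated data" the natural end-to-end
check. Given a response, verbal and physical indicators are drawn
independently (defaults 0.8 and 0.4) and redrawn until at least one is
set; the study-level analyses only use "any response", so this split is a
configurable guess.

Movement is *invented plumbing* (only distance is measured in the real
experiment, not modelled): a sticky Markov chain over the three bands
(stay 0.8, remainder split to neighbours), plus an approach bonus that
shifts 0.3 of each destination's probability one band nearer after a
response. Response probability deliberately has no state term, matching
the per-trial analysis model.

What the generator does *not* emulate: within-session escalation (the
response probability is time-invariant), real proxemics, any coupling
between personality and movement, and the verbal/physical split of real
participants. Passing tests therefore show that the pipeline and the
estimators behave correctly under the stated generative model, not that
the substantive findings would replicate on humans.

## Statistical models

With N = 13 trials per participant, response counts are overdispersed
relative to a Binomial (response probability drifts within a session), so
the per-participant count models use a Beta-Binomial in mean/scale form:
`resp_i ~ BetaBinomial(N, p_i φ, (1−p_i) φ)`, mean N p_i, φ > 0 the scale.

* Model A: `p_i = inv_logit(β₀ + β₁ · proprandom_i)`.
* Model B: `p_i = inv_logit(γ₀ + γ₁ M_i + γ₂ H_i)` with Medium/High
  dummies; derived per-level probabilities `p_none = inv_logit(γ₀)`,
  `p_medium = inv_logit(γ₀+γ₁)`, `p_high = inv_logit(γ₀+γ₂)` computed
  draw-by-draw (the plug-in-of-means version differs by Jensen's gap and
  is exposed only for worked examples).
* Model C: per-trial Bernoulli logistic,
  `η_i = u_id(i) + b_vl vl_i + b_pl pl_i + b_bu bu_i`, with the weights
  constrained to the unit simplex — the one-hot indicators sum to 1 on
  every row, so only the constrained combination is identified — and
  subject effects u_k ~ Normal(0, 1).

Priors: Normal(0, 10) on regression coefficients, Gamma(shape 2, rate
0.1) on φ (95% prior intervals −19.6..19.6 and 2.4..55.7), uniform on the
simplex (Dirichlet(1,1,1)) for the weights.

## Posterior computation

All models are sampled with coordinate slice sampling within Gibbs (Neal
2003: stepping-out plus shrinkage), over hand-written log posteriors, with
4 independent chains by default (2000 iterations for the count models,
8000 for the action model, first half discarded as warmup). Reasons and
details:

* The simplex is parameterised by a centred stick-breaking transform, so
  Σb = 1 and b ≥ 0 hold exactly for every draw; the uniform-simplex prior
  enters through the transform's log-Jacobian. φ is sampled on the log
  scale with its Jacobian.
* The count models are sampled with the intercept relocated to the
  covariate mean (priors evaluated on the original scale, draws mapped
  back exactly): coordinate updates mix poorly under strong
  intercept–slope correlation, and the centred chart removes it.
* In the action model the subject effects are conditionally independent
  given the weights, so all 45 are slice-updated in parallel; the two
  stick coordinates are updated against the full likelihood.
* Slice widths are order-of-magnitude only (stepping out adapts); the
  update caps stepping-out at 32 expansions and shrinkage at 100
  proposals, never reached in practice.
* Chains start overdispersed (SD 0.5) around a Nelder-Mead posterior mode
  for the count models and around a crude empirical-logit start for the
  action model.

The sampler was validated three ways: dense-grid integration of the
model A/B posteriors on fixed datasets (means and SDs agree within grid
error); an exact-conditional grid-Gibbs oracle for the full 45-subject
action model; and an importance-sampling check that the stick-breaking
Jacobian alone reproduces the uniform simplex. An earlier implementation
on an affine-invariant ensemble sampler was discarded after
simulation-based calibration exposed ~25% underestimation of posterior SD
in the 47-parameter model — a known weakness of ensemble moves in high
dimensions.

Convergence is summarised by split-R̂ (via arviz) per parameter; any
value above 1.05 attaches a warning to the returned draws (and gives the
`fit` command exit status 2, outputs still written). Constant parameters
yield R̂ = NaN, documented as the zero-variance sentinel. Posterior
summaries report mean, SD, equal-tail 2.5/97.5 percentiles and
`Prob > t` as the fraction of draws strictly greater than t.

Posterior predictive simulation draws, per simulated observation, one
posterior draw at random and cycles through the observed covariate rows;
the count models then draw the mixing probability from its Beta and the
count from the Binomial. Setting `binomial_only=True` skips the Beta step
(plug-in Binomial), which is how the package demonstrates that a plain
Binomial fits overdispersed counts poorly — we reuse the Beta-Binomial
fit's coefficient draws rather than refitting a separate
Binomial-likelihood model. The point-biserial model-fit summary
correlates observed per-trial y with the trial's posterior-predictive
mean response probability (Fisher-z 95% CI); a per-trial simulated-y
variant is available.

PSIS-LOO cross-validation is out of scope and not implemented.

## Calibration and the headline contrast

`recovery` runs the parameter-recovery loops: data are generated at fixed
reference values (β₀ = 1.34, β₁ = −1.45, φ = 1.17; γ = (−0.31, 0.79,
1.16), φ = 1.20; b = (0.59, 0.29, 0.12)) at study scale (45 × 13), each
replicate is fitted, and 95%-interval coverage is tallied. The acceptance
suite uses 100 replicates per model with 1000-iteration fits and tests
coverage compatibility with 0.95 by a two-sided binomial test at
α = 0.01. Two caveats are inherent rather than bugs: frequentist coverage
at a *fixed* truth is not guaranteed to equal the nominal level (prior
shrinkage matters when the likelihood is weak, and b_bu = 0.12 sits near
the simplex edge), and the per-replicate ordering of posterior means is
noisy — the ordering check is therefore made on replicate-averaged
posterior means, which separate cleanly (≈ 0.50 > 0.31 > 0.18).

The headline contrast — more policy, more interventions — is a small
effect under this generator: the simplex constraint caps the
best-versus-worst action gap at 0.47 on the logit scale, worth only a few
hundredths of a response per slot, while one 45-participant study has
group-mean noise of ~1 response. A single simulated study therefore often
violates the ordering, and the claim is about expectations. The estimator
averages 4000 replicated studies and reuses the same 15 sampled
participants in all three cohorts of a replication: each cohort's
marginal population is unchanged (so no group's expectation moves), but
participant-sampling noise cancels exactly in within-seed group
differences. Problem sizes (4000 studies; 1000 cohorts for the
proprandom sampling-theory check) were chosen to make the Monte-Carlo
error a fraction of the effects being measured.

## Degenerate inputs and numerical conventions

Distances must be finite and nonnegative; NaN/negative raise. `inv_logit`
is evaluated via `scipy.special.expit` (no overflow for |x| ≤ 700+).
Beta-Binomial pmf terms use log-gamma/log-beta throughout. An empty
dataset is legal for the count models and returns prior-only draws. A
saturated predictive probability (p = 0 or 1 at float precision) skips
the degenerate Beta draw and uses p directly. Event-log parsing reports
the first offending line number; booleans are serialised 0/1, enums by
name, a missing utterance index as an empty field.

## Known limitations

* The movement model is invented; nothing in the real study constrains it
  beyond the three bands existing.
* Fixed-truth coverage slightly below nominal for weakly identified
  parameters is expected and documented above, not corrected for.
* The slice-Gibbs sampler is serial per sweep; fits are seconds, full
  calibration loops minutes, on one CPU.
* Group-level effects produced by the generator are much smaller than the
  between-group differences reported for the human experiment; with
  45 participants the simulated pipeline demonstrates direction, not
  magnitude.
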