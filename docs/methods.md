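# Methods

## Model

The Continuous Correlated Beta Process (CCBP) keeps, for every dose dᵢ in a
discretised dosing domain and every binary response channel r (efficacy,
toxicity), a beta distribution Beta(α_{i,r}, β_{i,r}) over the response
probability. One participant's outcome at dose dⱼ adds the kernel
similarity K(dᵢ, dⱼ) ∈ (0, 1] to α (response seen) or β (response not seen)
of *every* dose. The update is pure addition, so batches of observations
commute, and the total pseudo-count mass any dose accrues equals the sum of
its kernel similarities to the tested doses (kernel-mass conservation —
checked in the tests to 1e−9 over 1000 observations). The tested dose
itself always gains exactly 1 (K(d, d) = 1), and as the kernel lengths
shrink to zero the rule degenerates to independent per-dose beta-binomial
counting, which is precisely what the naive comparator strategies use.

The efficacy and toxicity channels of one participant are treated as
statistically independent: a single observation updates both channels'
bookkeeping but no cross-channel coupling is modelled. Outcomes are likewise
sampled independently within a participant in the simulator.

### Kernel

The squared-exponential kernel
K(dᵢ, dⱼ) = exp(−Σ_o (d_{io} − d_{jo})² / l_o²) acts on dose components
already scaled to [0, 1]; no internal rescaling is performed. It factorises
across administration axes into a product of one-dimensional kernels, is
strictly positive at any finite separation (values are never thresholded to
zero — "completely dissimilar" is only a limit), and supports unequal
per-axis lengths although the defaults are equal: l = 0.2 for a single
administration, l₁ = l₂ = 0.25 for prime/boost, l₁ = l₂ = l₃ = 0.4 for
prime/boost/second-boost. These defaults are configuration inputs, not
fitted quantities; kernel-length estimation from data is out of scope. The
toxicity channel defaults to the efficacy kernel but may be given its own
lengths.

### Priors

The uninformative prior is Beta(1, 1) at every dose. An expert-informed
prior sets α⁰ = p·c + 1 and β⁰ = (1 − p)·c + 1 from the expert's predicted
response probability p and confidence c ≥ 0, so that the prior mode is
exactly p and c behaves as the number of participants' worth of data the
opinion is valued at; c = 0 recovers the flat prior. The study harness
builds "correct" priors by evaluating the scenario truth at every domain
dose and "incorrect" priors from its complement, with c = 3 (strong) or
c = 20 (very strong).

## Dose selection

Trial doses are chosen by Thompson sampling: one probability is drawn per
dose per channel from the current posteriors, utilities of the draws are
computed, and the argmax is dosed; the draw is repeated independently for
each of the c participants in a sampling cohort (c = 6 by default).
Interim/final nomination maximises utility at the posterior *medians*,
computed exactly via the inverse regularised incomplete beta function
rather than by sampling, so nomination is deterministic given the state;
exact utility ties are broken by a uniform draw. The sampled-utility path
never needs a tie-break in practice since beta draws are continuous.

## Utilities

*Maximum efficacy* is U = p_eff. The *utility contour* is
U = 1 − [((1−p_eff)/(1−anchor_eff))^ρ + (p_tox/anchor_tox)^ρ]^{1/ρ}; its
zero-utility level set passes exactly through (anchor_eff, 0) and
(1, anchor_tox), it is strictly increasing in p_eff and decreasing in
p_tox, and it is deliberately not clamped below zero — doses worse than the
zero-utility contour rank accordingly. The shipped anchors
(anchor_eff = 0.5, anchor_tox = 0.65, ρ = 2.0) are illustrative
clinician-style values; every simulation evaluates the scenario ground
truth and the strategy's internal predictions with the same spec instance,
so the choice cancels out of comparisons.

## Comparator strategies

**Parametric.** Dose-efficacy is a latent quadratic through the logistic
sigmoid, p(d) = σ(a + Σ_o b_o d_o − c_o d_o²), and dose-toxicity a latent
linear σ(a + Σ_o b_o d_o), defined for 1-D and 2-D domains (no 3-D
toxicity model is defined, so 3-D contour scenarios are unsupported for
this strategy). Both latents are linear in their parameters, so the fit is
a weighted logistic regression solved by L-BFGS-B on the exact negative
log-likelihood with analytic gradient, from three fixed starts (0, ±1 on
all coefficients) at tolerance 1e−8 — deterministic given the data.
Stability under separation (e.g. all responders) comes from pseudo-data:
one success and one failure, each with likelihood weight 0.5, at the
minimum, midpoint and maximum of the dose axis (corners plus centre for
multi-dose). Trial doses are drawn softmax-proportionally to
exp(U/T) over predicted utilities, default temperature T = 0.07 on the
[0, 1] utility scale — concentrated near the predicted optimum but still
exploring. Both the pseudo-data weight and T are configuration-exposed; the
defaults are this package's own calibration choices.

**Adaptive Naive** shares the CoBe selection rules but uses uncorrelated
counting on a coarse grid; **Uniform Naive** additionally abandons
adaptation, allocating every cohort evenly across the coarse grid (cohort
size therefore equals the domain size). Because a partial uniform cohort
cannot cover the domain exactly once, the uniform budget is floored to
whole cohorts (300 participants on a 9-dose grid → 33 cohorts, 297 used);
adaptive strategies instead truncate the final cohort when N is not a
multiple of c.

## Discretisation

Modelling strategies (CoBe, Parametric) use fine grids: 101 doses in 1-D,
a 21×21 grid (441 doses) in 2-D, an 11×11×11 grid (1331) in 3-D. Naive
strategies use 6, 9 (3×3) and 27 (3×3×3) doses respectively. Scenario
curves are closed forms evaluated lazily per dose, so fine and coarse grids
share one ground truth.

## Scenario generator

The catalogue re-creates qualitatively distinct dose-response shapes with
documented closed forms: Emax/Hill saturating curves (normalised so the
stated p_max is attained at the top of the axis), Gaussian-bump peaking
curves (quartic exponent for the flattened/plateau variant), a reversed
Hill for decreasing response, a bounded trend-plus-sinusoid for undulating
response, and, for multi-administration domains, per-axis Hill/bump latents
composed additively with interaction terms (synergy, antagonism, high-dose
decline, axis dominance, a dose-total bump for the
"two-of-three-maximal" surface). Every constructor validates its output
lies in [0, 1] on a dense grid and carries a shape assertion (monotone /
interior peak / multimodal / plateau / corner ordering) exercised by the
tests. Default parameters are fixed once per tag: most curves span ≈0.05 to
0.9 response probability, matching the dynamic range typical of published
dose-ranging summaries; the sharply peaking curve (peak 0.5, width 0.1)
deliberately places its optimum off the coarse 6-dose grid with a gap
≥ 0.05, the regime in which modelling approaches should beat coarse-grid
counting. Outcomes are Bernoulli draws from the curves.

What the generator does *not* emulate: participant heterogeneity,
time-varying responses, correlated efficacy/toxicity within a participant,
non-binary immunological readouts, and dropout. Passing tests therefore
demonstrate algorithmic correctness and comparative behaviour under clean
binomial sampling, not performance on real trial data.

## Simulation study engine

A trial of N participants runs in cohorts; after every cohort the strategy
nominates an interim optimal dose, and two metrics are recorded: the
ground-truth efficacy/utility at the nominated dose, and the cumulative
benefit (count of efficacious responders, or n·U of the empirical response
fractions under the contour). Replicates are aggregated into per-cohort
means with 95% confidence intervals — Student-t on the replicate means by
default, percentile bootstrap (2000 resamples) as a config switch, the two
agreeing to ~10% relative width at 100 replicates in the tests. Reference
lines accompany every aggregate: the scenario's maximum/minimum achievable
metric, and n·max / n·min for the cumulative metric; no strategy can
exceed the upper line.

Reproducibility: every replicate derives its generator from
(study seed, CRC-32 of the scenario tag, CRC-32 of the strategy name,
replicate index) via `numpy.random.SeedSequence`, so runs are bitwise
reproducible and adding scenarios or strategies never perturbs existing
streams.

Problem sizes in the shipped test-suite are deliberately modest — 20
replicates of N = 300 for the strategy comparison and 50 first-cohort
replicates for the expert-prior orderings — chosen as the smallest sizes at
which the qualitative orderings are stable across seeds; the library itself
runs the full 100-replicate study via `run_study` or the `cobedose study`
command.

## Numerical choices

* Posterior medians and credible intervals: `scipy.stats.beta` quantiles
  (inverse incomplete beta), not sampling.
* Kernel mass accumulates by plain summation; conservation tolerance 1e−9
  for up to ~10⁴ observations.
* Exact-tie nomination: uniform draw among tied argmaxes from the
  strategy's own stream.
* Correlated updates accept doses outside the discretised domain (the
  kernel is continuous); only the uncorrelated rule requires membership.
* Degenerate inputs are rejected loudly: empty domains, out-of-range
  probabilities, non-positive kernel lengths, observations with no recorded
  response, uniform cohorts of the wrong size.

## Known limitations

No stopping rules or escalation/de-escalation constraints; binary outcomes
only; efficacy/toxicity independence within participants; kernel lengths
fixed rather than learned; the contour anchors are illustrative defaults;
single-process execution.
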