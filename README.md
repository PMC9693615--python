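# cobedose

Adaptive vaccine dose-optimisation trial simulation built around the
**Correlated Beta (CoBe)** approach: a non-parametric Continuous Correlated
Beta Process (CCBP) dose-response model driven by Thompson sampling.

## The problem

Choosing a vaccine dose is hard: for some vaccines efficacy saturates with
dose, for others there is an interior maximum after which more vaccine means
*less* efficacy, and toxicity typically rises with dose. Early-phase trials
are small (tens to a few hundred participants), so committing to a
parametric dose-response curve that turns out to be misspecified can send
the whole programme to a suboptimal dose. This package is for
biostatisticians and trial modellers who want to study — by simulation —
how well different adaptive dose-optimisation approaches locate an optimal
dose under uncertainty about the curve shape, for single-administration and
prime/boost (and second-boost) vaccines.

## The model

The dosing domain is a finite grid of doses, each dose a vector
d = (d₁, …, d_H) of H ∈ {1, 2, 3} administrations scaled to [0, 1]. For
each dose dᵢ and each binary response r ∈ {efficacy, toxicity} the CCBP
keeps a beta distribution

    p_{i,r} ~ Beta(α_{i,r}, β_{i,r}),      α⁰ = β⁰ = 1 (uninformative),

and an observation at dose dⱼ updates *every* dose by a fractional
pseudo-count equal to a similarity kernel:

    response observed:      α_{i,r} ← α_{i,r} + K(dᵢ, dⱼ)
    response not observed:  β_{i,r} ← β_{i,r} + K(dᵢ, dⱼ)

with the squared-exponential kernel
K(dᵢ, dⱼ) = exp(−Σ_o (d_{io} − d_{jo})² / l_o²) (defaults l = 0.2, 0.25,
0.4 per axis for 1-, 2-, 3-administration domains). The only modelling
assumption is *similar doses give similar responses*. Expert opinion enters
through the prior α⁰ = p·c + 1, β⁰ = (1−p)·c + 1, whose mode is the
expert's predicted probability p and whose weight c is the number of
participants the opinion is worth.

A trial runs in cohorts: trial doses are chosen by **Thompson sampling**
(draw one probability per dose from each posterior, dose the participant at
the argmax of the sampled utilities), and the interim/final optimal dose is
the argmax of utility at the posterior **medians**. Utility is either plain
efficacy, U = p_eff, or an efficacy–toxicity trade-off contour

    U = 1 − [((1−p_eff)/(1−anchor_eff))^ρ + (p_tox/anchor_tox)^ρ]^{1/ρ},

whose zero-utility contour passes through (anchor_eff, 0) and
(1, anchor_tox).

Three comparator approaches are included: **Parametric** (latent-quadratic
efficacy / latent-linear toxicity maximum-likelihood fits with stabilising
pseudo-data and softmax dose selection), **Adaptive Naive** (Thompson
sampling with uncorrelated per-dose beta counting on a coarse grid) and
**Uniform Naive** (even allocation over the coarse grid, no adaptation).
A scenario catalogue supplies closed-form ground-truth surfaces (saturating,
peaking, undulating, synergistic, antagonistic, …) and the simulation engine
runs replicated trials and reports per-cohort means with 95% confidence
intervals against the theoretical best/worst reference lines.

## Worked example

The core update, by hand: two doses with flat Beta(1, 1) priors whose
kernel similarity is 0.5; one participant dosed at the first dose responds.

```python
import numpy as np
from cobedose import (DosingDomain, KernelSpec, Observation,
                      init_uninformative, update)

spec = KernelSpec((0.2,))
sep = 0.2 * np.sqrt(np.log(2))          # separation with similarity 0.5
domain = DosingDomain([[0.0], [sep]])
state = init_uninformative(domain, ("efficacy",))
update(state, Observation((0.0,), efficacy=1), spec)
print(state.alpha[:, 0])                # [2.  1.5]
```

The tested dose gains a full success count (Beta(2, 1)); the half-similar
dose gains half a count (Beta(1.5, 1)) — information propagates to doses
never tested.

A small simulation from the shell — 5 replicate trials of 60 participants,
CoBe on a sharply peaking dose-efficacy curve (true optimum 0.9 at dose
0.5, a dose the coarse naive grids cannot even test):

```sh
$ cobedose report --scenario sharply_peaking --doa cobe \
    --n-participants 60 --reps 5 --seed 3 --out out/
cobe on sharply_peaking: mean true metric 0.8783 [0.8582, 0.8984] at n=60 (scenario max 0.9000)
wrote out/aggregate.csv
```

After only 60 participants the nominated dose's true efficacy averages
0.878 of an achievable 0.9: the approach has located the narrow interior
peak. `out/aggregate.csv` holds the full per-cohort trajectory (means, CIs,
reference lines).

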