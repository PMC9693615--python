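"""The four dose-optimisation approaches (DOAs) as pluggable strategies.

A dose-optimisation approach combines a dose-response model, a trial-dose
selection rule, a final-dose selection rule, and a dosing-domain
discretisation.  All four share one interface: ``propose_cohort`` returns
the next batch of trial doses, ``observe`` absorbs the resulting outcomes,
and ``nominate`` names the currently-best dose.

* **CoBe** — Continuous Correlated Beta Process posterior over a fine grid,
  Thompson sampling for trial doses, maximum utility of the posterior
  medians for nomination.
* **Adaptive Naive** — identical selection rules, but uncorrelated per-dose
  beta counting on a coarse grid (no similarity kernel).
* **Parametric** — latent-quadratic dose-efficacy and latent-linear
  dose-toxicity models fit by maximum likelihood (stabilised with
  pseudo-data), softmax trial-dose selection over predicted utility, argmax
  of predicted utility for nomination.
* **Uniform Naive** — non-adaptive: every cohort spreads participants evenly
  over the coarse grid; nomination as Adaptive Naive.

Strategies work in dose *indices* into their trial domain; the trial and
prediction domains coincide in this package.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from . import ccbp
from .ccbp import BetaState, ExpertPrior, Observation
from .kernels import DosingDomain, KernelSpec
from .utility import UtilitySpec, utility_vector

__all__ = [
    "DoseOptimisationStrategy",
    "CoBeStrategy",
    "AdaptiveNaiveStrategy",
    "ParametricStrategy",
    "UniformNaiveStrategy",
    "latent_quadratic",
    "latent_linear",
    "fit_parametric",
    "make_pseudo_data",
    "softmax_probabilities",
    "uniform_naive_allocate",
    "make_strategy",
    "FitError",
    "DEFAULT_TEMPERATURE",
    "DEFAULT_PSEUDO_WEIGHT",
]

DEFAULT_TEMPERATURE = 0.07
DEFAULT_PSEUDO_WEIGHT = 0.5


def argmax_random_ties(values: np.ndarray, rng: np.random.Generator) -> int:
    """Index of the maximum, exact ties resolved by a uniform draw."""
    values = np.asarray(values)
    ties = np.flatnonzero(values == values.max())
    if ties.size == 1:
        return int(ties[0])
    return int(rng.choice(ties))


class DoseOptimisationStrategy(ABC):
    """Common interface: propose a cohort, absorb outcomes, nominate a dose."""

    name: str

    def __init__(self, trial_domain: DosingDomain, utility: UtilitySpec):
        self.trial_domain = trial_domain
        self.prediction_domain = trial_domain
        self.utility = utility

    @property
    def responses(self) -> tuple[str, ...]:
        if self.utility.needs_toxicity:
            return ("efficacy", "toxicity")
        return ("efficacy",)

    #: Cohort size this strategy requires, or None if any size is accepted.
    required_cohort_size: Optional[int] = None

    @abstractmethod
    def propose_cohort(self, c: int, rng: np.random.Generator) -> np.ndarray:
        """Indices (into the trial domain) of the next ``c`` trial doses."""

    @abstractmethod
    def observe(self, observations: Sequence[Observation]) -> None:
        """Absorb a batch of trial outcomes."""

    @abstractmethod
    def nominate(self, rng: np.random.Generator) -> int:
        """Index (into the prediction domain) of the currently-best dose."""


# ---------------------------------------------------------------------------
# Thompson-sampling strategies on beta posteriors (CoBe and Adaptive Naive)


class _ThompsonBetaStrategy(DoseOptimisationStrategy):
    """Shared machinery: beta state, Thompson proposals, median nomination."""

    def __init__(
        self,
        trial_domain: DosingDomain,
        utility: UtilitySpec,
        prior: Optional[dict[str, ExpertPrior]] = None,
    ):
        super().__init__(trial_domain, utility)
        if prior:
            self.state: BetaState = ccbp.init_expert(trial_domain, prior, self.responses)
        else:
            self.state = ccbp.init_uninformative(trial_domain, self.responses)

    def _sampled_utilities(self, c: int, rng: np.random.Generator) -> np.ndarray:
        """(c, n_doses) utilities from independent posterior draws."""
        j = self.state.response_index("efficacy")
        p_eff = rng.beta(
            self.state.alpha[:, j], self.state.beta[:, j], size=(c, len(self.trial_domain))
        )
        p_tox = None
        if self.utility.needs_toxicity:
            k = self.state.response_index("toxicity")
            p_tox = rng.beta(
                self.state.alpha[:, k], self.state.beta[:, k], size=p_eff.shape
            )
        return utility_vector(p_eff, p_tox, self.utility)

    def propose_cohort(self, c: int, rng: np.random.Generator) -> np.ndarray:
        if c < 1:
            raise ValueError("cohort size must be at least 1")
        # beta draws are continuous, so sampled-utility ties are null events
        return np.argmax(self._sampled_utilities(c, rng), axis=1)

    def nominate(self, rng: np.random.Generator) -> int:
        p_eff = ccbp.medians(self.state, "efficacy")
        p_tox = (
            ccbp.medians(self.state, "toxicity") if self.utility.needs_toxicity else None
        )
        return argmax_random_ties(utility_vector(p_eff, p_tox, self.utility), rng)


class CoBeStrategy(_ThompsonBetaStrategy):
    """Correlated Beta approach: kernelised updates over a fine dosing grid."""

    name = "cobe"

    def __init__(
        self,
        trial_domain: DosingDomain,
        utility: UtilitySpec,
        kernel_eff: Optional[KernelSpec] = None,
        kernel_tox: Optional[KernelSpec] = None,
        prior: Optional[dict[str, ExpertPrior]] = None,
    ):
        super().__init__(trial_domain, utility, prior)
        self.kernel_eff = kernel_eff or KernelSpec.default(trial_domain.ndim)
        # toxicity kernel defaults to the efficacy kernel
        self.kernel_tox = kernel_tox or self.kernel_eff

    def observe(self, observations: Sequence[Observation]) -> None:
        same = self.kernel_tox == self.kernel_eff
        for obs in observations:
            if same or not self.utility.needs_toxicity:
                ccbp.update(self.state, obs, self.kernel_eff)
                continue
            # split channels so each uses its own kernel lengths; one
            # participant still counts as one observation
            n0 = self.state.n_obs
            if obs.efficacy is not None:
                ccbp.update(
                    self.state, Observation(obs.dose, efficacy=obs.efficacy), self.kernel_eff
                )
            if obs.toxicity is not None:
                ccbp.update(
                    self.state, Observation(obs.dose, toxicity=obs.toxicity), self.kernel_tox
                )
            self.state.n_obs = n0 + 1


class AdaptiveNaiveStrategy(_ThompsonBetaStrategy):
    """Thompson sampling with uncorrelated beta counting on a coarse grid."""

    name = "adaptive_naive"

    def observe(self, observations: Sequence[Observation]) -> None:
        for obs in observations:
            ccbp.update_uncorrelated(self.state, obs)


# ---------------------------------------------------------------------------
# Parametric strategy: latent-quadratic / latent-linear MLE with pseudo-data


class FitError(RuntimeError):
    """Optimiser failed to converge; carries the best parameters found."""

    def __init__(self, message: str, params: np.ndarray):
        super().__init__(message)
        self.params = params


def _design_matrix(kind: str, doses: np.ndarray) -> np.ndarray:
    """Linear design for the latent predictor z = X @ theta.

    Efficacy (latent quadratic), per axis o: ... + b_o d_o - c_o d_o^2, so
    columns are [1] + [d_o, -d_o^2] per axis.  Toxicity (latent linear):
    [1] + [d_o] per axis, defined for 1-D and 2-D domains only.
    """
    doses = np.atleast_2d(np.asarray(doses, dtype=float))
    ndim = doses.shape[1]
    cols = [np.ones(len(doses))]
    if kind == "efficacy":
        for o in range(ndim):
            cols.extend([doses[:, o], -doses[:, o] ** 2])
    elif kind == "toxicity":
        if ndim > 2:
            raise ValueError("the latent-linear toxicity model covers 1-D and 2-D domains only")
        for o in range(ndim):
            cols.append(doses[:, o])
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return np.column_stack(cols)


def latent_quadratic(doses: np.ndarray, params: Sequence[float]) -> np.ndarray:
    """Dose-efficacy curve: inverse-logit of a per-axis quadratic.

    1-D params (a, b, c): sigmoid(a + b d - c d^2); 2-D (a, b1, c1, b2, c2);
    3-D adds (b3, c3).
    """
    doses = np.atleast_2d(np.asarray(doses, dtype=float))
    X = _design_matrix("efficacy", doses)
    params = np.asarray(params, dtype=float)
    if params.shape[0] != X.shape[1]:
        raise ValueError(
            f"expected {X.shape[1]} parameters for a {doses.shape[1]}-D quadratic, "
            f"got {params.shape[0]}"
        )
    return expit(X @ params)


def latent_linear(doses: np.ndarray, params: Sequence[float]) -> np.ndarray:
    """Dose-toxicity curve: inverse-logit of a linear predictor (1-D/2-D)."""
    doses = np.atleast_2d(np.asarray(doses, dtype=float))
    X = _design_matrix("toxicity", doses)
    params = np.asarray(params, dtype=float)
    if params.shape[0] != X.shape[1]:
        raise ValueError(
            f"expected {X.shape[1]} parameters for a {doses.shape[1]}-D linear model, "
            f"got {params.shape[0]}"
        )
    return expit(X @ params)


def make_pseudo_data(
    ndim: int, weight: float = DEFAULT_PSEUDO_WEIGHT
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stabilising pseudo-observations for the maximum-likelihood fit.

    One success and one failure, each with likelihood weight ``weight``, at
    the minimum, midpoint and maximum of the dose axis (1-D), or at the
    corners plus the centre of the dose hypercube (multi-dose).  Guarantees
    a proper optimum even under complete separation or no data.

    Returns (doses, outcomes, weights).
    """
    if ndim == 1:
        anchors = np.array([[0.0], [0.5], [1.0]])
    else:
        corners = np.array(
            np.meshgrid(*([[0.0, 1.0]] * ndim), indexing="ij")
        ).reshape(ndim, -1).T
        anchors = np.vstack([corners, np.full((1, ndim), 0.5)])
    doses = np.repeat(anchors, 2, axis=0)
    outcomes = np.tile([1.0, 0.0], len(anchors))
    weights = np.full(len(doses), float(weight))
    return doses, outcomes, weights


#: Fixed multi-start initial points for the MLE (origin plus gentle slopes).
_MLE_STARTS = (0.0, 1.0, -1.0)


def fit_parametric(
    kind: str,
    doses: np.ndarray,
    outcomes: np.ndarray,
    ndim: Optional[int] = None,
    pseudo_weight: float = DEFAULT_PSEUDO_WEIGHT,
    tol: float = 1e-8,
) -> np.ndarray:
    """Maximum-likelihood parameters of a latent model given binary data.

    Maximises the weighted Bernoulli log-likelihood of the real observations
    (unit weight) plus the stabilising pseudo-data.  Deterministic: fixed
    multi-starts, fixed tolerance.  Raises :class:`FitError` (carrying the
    best parameters found) if no start converges.
    """
    doses = np.atleast_2d(np.asarray(doses, dtype=float))
    outcomes = np.asarray(outcomes, dtype=float)
    if ndim is None:
        ndim = doses.shape[1]
    pd_doses, pd_y, pd_w = make_pseudo_data(ndim, pseudo_weight)
    if doses.size:
        all_doses = np.vstack([doses, pd_doses])
        y = np.concatenate([outcomes, pd_y])
        w = np.concatenate([np.ones(len(doses)), pd_w])
    else:
        all_doses, y, w = pd_doses, pd_y, pd_w

    X = _design_matrix(kind, all_doses)

    def nll_and_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        z = X @ theta
        # log(1 + e^z) - y z, numerically stable
        nll = float(np.sum(w * (np.logaddexp(0.0, z) - y * z)))
        grad = X.T @ (w * (expit(z) - y))
        return nll, grad

    best = None
    converged = False
    for start in _MLE_STARTS:
        theta0 = np.full(X.shape[1], start, dtype=float)
        res = minimize(nll_and_grad, theta0, jac=True, method="L-BFGS-B", tol=tol)
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    if not converged:
        raise FitError("maximum-likelihood fit did not converge", best.x)
    return best.x


def softmax_probabilities(utilities: np.ndarray, temperature: float) -> np.ndarray:
    """Selection probabilities proportional to exp(U / temperature)."""
    if temperature <= 0:
        raise ValueError("softmax temperature must be positive")
    z = np.asarray(utilities, dtype=float) / temperature
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


class ParametricStrategy(DoseOptimisationStrategy):
    """Parametric approach: MLE curve fits plus softmax dose selection."""

    name = "parametric"

    def __init__(
        self,
        trial_domain: DosingDomain,
        utility: UtilitySpec,
        temperature: float = DEFAULT_TEMPERATURE,
        pseudo_weight: float = DEFAULT_PSEUDO_WEIGHT,
    ):
        super().__init__(trial_domain, utility)
        if utility.needs_toxicity and trial_domain.ndim > 2:
            raise ValueError(
                "no latent-linear toxicity model is defined for 3-D domains"
            )
        if temperature <= 0:
            raise ValueError("softmax temperature must be positive")
        self.temperature = temperature
        self.pseudo_weight = pseudo_weight
        self.observations: list[Observation] = []
        self._cache: Optional[dict[str, np.ndarray]] = None

    def observe(self, observations: Sequence[Observation]) -> None:
        self.observations.extend(observations)
        self._cache = None

    def _fitted_params(self) -> dict[str, np.ndarray]:
        if self._cache is None:
            params = {}
            for kind in self.responses:
                records = [
                    (obs.dose, getattr(obs, kind))
                    for obs in self.observations
                    if getattr(obs, kind) is not None
                ]
                doses = np.array([r[0] for r in records], dtype=float).reshape(
                    -1, self.trial_domain.ndim
                )
                y = np.array([r[1] for r in records], dtype=float)
                params[kind] = fit_parametric(
                    kind, doses, y, ndim=self.trial_domain.ndim,
                    pseudo_weight=self.pseudo_weight,
                )
            self._cache = params
        return self._cache

    def predicted_utilities(self) -> np.ndarray:
        """Utility of the fitted curves at every trial-domain dose."""
        params = self._fitted_params()
        p_eff = latent_quadratic(self.trial_domain.doses, params["efficacy"])
        p_tox = None
        if self.utility.needs_toxicity:
            p_tox = latent_linear(self.trial_domain.doses, params["toxicity"])
        return utility_vector(p_eff, p_tox, self.utility)

    def propose_cohort(self, c: int, rng: np.random.Generator) -> np.ndarray:
        if c < 1:
            raise ValueError("cohort size must be at least 1")
        probs = softmax_probabilities(self.predicted_utilities(), self.temperature)
        return rng.choice(len(self.trial_domain), size=c, p=probs)

    def nominate(self, rng: np.random.Generator) -> int:
        return argmax_random_ties(self.predicted_utilities(), rng)


# ---------------------------------------------------------------------------
# Uniform Naive strategy


def uniform_naive_allocate(domain: DosingDomain, cohort_index: int = 0) -> np.ndarray:
    """Indices of one uniform cohort: every domain dose exactly once, in order.

    Independent of the data and of ``cohort_index`` (kept for interface
    symmetry): the allocation never adapts.
    """
    return np.arange(len(domain))


class UniformNaiveStrategy(DoseOptimisationStrategy):
    """Non-adaptive strategy: spread each cohort evenly over the coarse grid.

    The sampling-cohort size must equal the domain size (6, 9 or 27);
    nomination uses the uncorrelated-beta posterior medians, as the Adaptive
    Naive strategy does.
    """

    name = "uniform_naive"

    def __init__(
        self,
        trial_domain: DosingDomain,
        utility: UtilitySpec,
        prior: Optional[dict[str, ExpertPrior]] = None,
    ):
        super().__init__(trial_domain, utility)
        self.required_cohort_size = len(trial_domain)
        if prior:
            self.state = ccbp.init_expert(trial_domain, prior, self.responses)
        else:
            self.state = ccbp.init_uninformative(trial_domain, self.responses)
        self._cohorts_proposed = 0

    def propose_cohort(self, c: int, rng: np.random.Generator) -> np.ndarray:
        if c != len(self.trial_domain):
            raise ValueError(
                f"uniform allocation needs cohort size {len(self.trial_domain)}, got {c}"
            )
        idx = uniform_naive_allocate(self.trial_domain, self._cohorts_proposed)
        self._cohorts_proposed += 1
        return idx

    def observe(self, observations: Sequence[Observation]) -> None:
        for obs in observations:
            ccbp.update_uncorrelated(self.state, obs)

    def nominate(self, rng: np.random.Generator) -> int:
        p_eff = ccbp.medians(self.state, "efficacy")
        p_tox = (
            ccbp.medians(self.state, "toxicity") if self.utility.needs_toxicity else None
        )
        return argmax_random_ties(utility_vector(p_eff, p_tox, self.utility), rng)


# ---------------------------------------------------------------------------
# factory


STRATEGY_NAMES = ("cobe", "parametric", "adaptive_naive", "uniform_naive")

#: Coarse-grid points per axis for the naive strategies, by dimensionality.
_COARSE_POINTS = {1: 6, 2: 3, 3: 3}


def make_strategy(
    name: str,
    fine_domain: DosingDomain,
    utility: UtilitySpec,
    prior: Optional[dict[str, ExpertPrior]] = None,
    coarse_domain: Optional[DosingDomain] = None,
    **kwargs,
) -> DoseOptimisationStrategy:
    """Build a fresh strategy by name.

    Modelling strategies (cobe, parametric) operate on ``fine_domain``; the
    naive strategies on ``coarse_domain`` (default: the standard 6 / 9 / 27
    grid for the dimensionality).  Extra keyword arguments go to the
    strategy constructor (kernel specs, temperature, ...).
    """
    if name == "cobe":
        return CoBeStrategy(fine_domain, utility, prior=prior, **kwargs)
    if name == "parametric":
        return ParametricStrategy(fine_domain, utility, **kwargs)
    if coarse_domain is None:
        coarse_domain = DosingDomain.regular_grid(
            _COARSE_POINTS[fine_domain.ndim], fine_domain.ndim
        )
    if name == "adaptive_naive":
        return AdaptiveNaiveStrategy(coarse_domain, utility, prior=prior, **kwargs)
    if name == "uniform_naive":
        return UniformNaiveStrategy(coarse_domain, utility, prior=prior, **kwargs)
    raise ValueError(f"unknown strategy {name!r}; known: {STRATEGY_NAMES}")
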