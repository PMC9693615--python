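"""Continuous Correlated Beta Process (CCBP) state and updates.

The CCBP places an independent beta distribution Beta(alpha_i, beta_i) on the
response probability of every dose in a discretised dosing domain, for each
binary response channel (efficacy, toxicity).  An observation at dose d_j
adds the kernel similarity K(d_i, d_j) to alpha_i (response seen) or beta_i
(response not seen) of *every* dose d_i — a fractional pseudo-count.  With
the degenerate "self-only" kernel this reduces to ordinary per-dose
beta-binomial counting, which is exactly the bookkeeping the naive
strategies use.

Priors are either uninformative, Beta(1, 1) everywhere, or expert-informed:

    alpha0 = p_expert * c_expert + 1,   beta0 = (1 - p_expert) * c_expert + 1,

so the prior mode equals the expert's predicted probability and c_expert is
the number of participants' worth of data the expert opinion is valued at.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kernels import DosingDomain, KernelSpec, kernel_row

__all__ = [
    "RESPONSE_TYPES",
    "Observation",
    "ExpertPrior",
    "BetaState",
    "init_uninformative",
    "init_expert",
    "update",
    "update_uncorrelated",
    "median",
    "medians",
    "sample_probs",
    "credible_interval",
]

#: The two binary response channels modelled in this package.
RESPONSE_TYPES: tuple[str, ...] = ("efficacy", "toxicity")


@dataclass(frozen=True)
class Observation:
    """One participant's trial record: the dose given and binary outcomes.

    Either outcome may be ``None`` (not recorded), but not both.
    """

    dose: tuple[float, ...]
    efficacy: Optional[int] = None
    toxicity: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose", tuple(float(x) for x in self.dose))
        if self.efficacy is None and self.toxicity is None:
            raise ValueError("observation must record at least one response")
        for name in ("efficacy", "toxicity"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise ValueError(f"{name} outcome must be 0, 1 or None, got {v!r}")


@dataclass(frozen=True)
class ExpertPrior:
    """Per-dose expert prediction ``p_expert`` with confidence ``c_expert``.

    ``c_expert[i]`` >= 0 acts as the number of observations at dose i the
    expert opinion is worth; 0 recovers the uninformative prior.
    """

    p_expert: np.ndarray
    c_expert: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p_expert, dtype=float)
        c = np.asarray(self.c_expert, dtype=float)
        if p.shape != c.shape or p.ndim != 1:
            raise ValueError("p_expert and c_expert must be 1-D vectors of equal length")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("expert probabilities must lie in [0, 1]")
        if np.any(c < 0):
            raise ValueError("expert confidences must be non-negative")
        object.__setattr__(self, "p_expert", p)
        object.__setattr__(self, "c_expert", c)


class BetaState:
    """Per-dose, per-response beta parameters of a CCBP.

    Attributes
    ----------
    alpha, beta : ndarray, shape (n_doses, n_responses)
        Current beta parameters; columns follow ``responses`` order.
    alpha0, beta0 : ndarray
        The prior parameters (frozen at construction).
    n_obs : int
        Number of observations absorbed.
    """

    def __init__(
        self,
        domain: DosingDomain,
        responses: Sequence[str],
        alpha0: np.ndarray,
        beta0: np.ndarray,
    ):
        responses = tuple(responses)
        if not responses or any(r not in RESPONSE_TYPES for r in responses):
            raise ValueError(f"responses must be a non-empty subset of {RESPONSE_TYPES}")
        shape = (len(domain), len(responses))
        alpha0 = np.broadcast_to(np.asarray(alpha0, dtype=float), shape).copy()
        beta0 = np.broadcast_to(np.asarray(beta0, dtype=float), shape).copy()
        if np.any(alpha0 <= 0) or np.any(beta0 <= 0):
            raise ValueError("beta parameters must be positive")
        self.domain = domain
        self.responses = responses
        self.alpha0 = alpha0
        self.beta0 = beta0
        self.alpha = alpha0.copy()
        self.beta = beta0.copy()
        self.n_obs = 0

    def response_index(self, response: str) -> int:
        try:
            return self.responses.index(response)
        except ValueError:
            raise KeyError(f"state does not track response {response!r}") from None

    def copy(self) -> "BetaState":
        out = BetaState(self.domain, self.responses, self.alpha0, self.beta0)
        out.alpha = self.alpha.copy()
        out.beta = self.beta.copy()
        out.n_obs = self.n_obs
        return out

    # -- serialisation ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tabular snapshot: dose components, response, alpha, beta."""
        rows = []
        for r_idx, r in enumerate(self.responses):
            for i in range(len(self.domain)):
                row = {f"dose_{o + 1}": self.domain.doses[i, o] for o in range(self.domain.ndim)}
                row.update(response=r, alpha=self.alpha[i, r_idx], beta=self.beta[i, r_idx])
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


def init_uninformative(
    domain: DosingDomain, responses: Sequence[str] = ("efficacy",)
) -> BetaState:
    """Flat Beta(1, 1) prior on every dose for every tracked response."""
    return BetaState(domain, responses, alpha0=np.array(1.0), beta0=np.array(1.0))


def init_expert(
    domain: DosingDomain,
    priors: dict[str, ExpertPrior],
    responses: Sequence[str] = ("efficacy",),
) -> BetaState:
    """Expert-informed prior: alpha0 = p*c + 1, beta0 = (1-p)*c + 1 per dose.

    ``priors`` maps response label -> :class:`ExpertPrior`; responses without
    an entry keep the uninformative Beta(1, 1).
    """
    responses = tuple(responses)
    alpha0 = np.ones((len(domain), len(responses)))
    beta0 = np.ones_like(alpha0)
    for r, prior in priors.items():
        if r not in responses:
            raise KeyError(f"prior given for untracked response {r!r}")
        if prior.p_expert.shape[0] != len(domain):
            raise ValueError("expert prior length does not match the domain")
        j = responses.index(r)
        alpha0[:, j] = prior.p_expert * prior.c_expert + 1.0
        beta0[:, j] = (1.0 - prior.p_expert) * prior.c_expert + 1.0
    return BetaState(domain, responses, alpha0, beta0)


def update(state: BetaState, obs: Observation, spec: KernelSpec) -> BetaState:
    """Absorb one observation with correlated (kernelised) pseudo-counts.

    For every tracked response recorded in ``obs`` and every domain dose i,
    adds K(d_i, d_obs) to alpha (response observed) or to beta (response not
    observed).  Pure addition, so batches commute.  Mutates and returns
    ``state``.  The observed dose need not belong to the domain.
    """
    row = None
    touched = False
    for r_idx, r in enumerate(state.responses):
        outcome = getattr(obs, r)
        if outcome is None:
            continue
        if row is None:
            row = kernel_row(obs.dose, state.domain, spec)
        if outcome == 1:
            state.alpha[:, r_idx] += row
        else:
            state.beta[:, r_idx] += row
        touched = True
    if not touched:
        raise ValueError(
            f"observation records none of the tracked responses {state.responses}"
        )
    state.n_obs += 1
    return state


def update_uncorrelated(state: BetaState, obs: Observation) -> BetaState:
    """Absorb one observation with the self-only (identity) kernel.

    Only the tested dose's parameters change, by exactly 1 — ordinary
    beta-binomial counting, as used by the naive strategies.  The observed
    dose must be a member of the domain.
    """
    i = state.domain.index_of(obs.dose)
    touched = False
    for r_idx, r in enumerate(state.responses):
        outcome = getattr(obs, r)
        if outcome is None:
            continue
        if outcome == 1:
            state.alpha[i, r_idx] += 1.0
        else:
            state.beta[i, r_idx] += 1.0
        touched = True
    if not touched:
        raise ValueError(
            f"observation records none of the tracked responses {state.responses}"
        )
    state.n_obs += 1
    return state


def median(state: BetaState, dose_index: int, response: str) -> float:
    """Exact posterior median via the inverse regularised incomplete beta."""
    j = state.response_index(response)
    return float(stats.beta.median(state.alpha[dose_index, j], state.beta[dose_index, j]))


def medians(state: BetaState, response: str) -> np.ndarray:
    """Vector of posterior medians for every dose (deterministic)."""
    j = state.response_index(response)
    return stats.beta.median(state.alpha[:, j], state.beta[:, j])


def sample_probs(
    state: BetaState, response: str, rng: np.random.Generator
) -> np.ndarray:
    """One independent draw p-hat_i ~ Beta(alpha_i, beta_i) per dose."""
    j = state.response_index(response)
    return rng.beta(state.alpha[:, j], state.beta[:, j])


def credible_interval(
    state: BetaState, dose_index: int, response: str, level: float = 0.95
) -> tuple[float, float]:
    """Equal-tailed credible interval of the per-dose beta posterior."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly inside (0, 1)")
    j = state.response_index(response)
    a = state.alpha[dose_index, j]
    b = state.beta[dose_index, j]
    tail = (1.0 - level) / 2.0
    return (float(stats.beta.ppf(tail, a, b)), float(stats.beta.ppf(1.0 - tail, a, b)))


def observations_to_frame(observations: Sequence[Observation]) -> pd.DataFrame:
    """Observation log as a table with 0/1/empty outcome cells."""
    if not observations:
        return pd.DataFrame(columns=["dose_1", "efficacy", "toxicity"])
    ndim = len(observations[0].dose)
    rows = []
    for obs in observations:
        row = {f"dose_{o + 1}": obs.dose[o] for o in range(ndim)}
        row["efficacy"] = obs.efficacy
        row["toxicity"] = obs.toxicity
        rows.append(row)
    return pd.DataFrame(rows)


def observations_from_frame(frame: pd.DataFrame) -> list[Observation]:
    dose_cols = [c for c in frame.columns if c.startswith("dose_")]
    out = []
    for _, row in frame.iterrows():
        def _cell(name: str) -> Optional[int]:
            v = row.get(name)
            return None if v is None or pd.isna(v) else int(v)

        out.append(
            Observation(
                dose=tuple(float(row[c]) for c in dose_cols),
                efficacy=_cell("efficacy"),
                toxicity=_cell("toxicity"),
            )
        )
    return out


def observations_from_csv(path_or_buf) -> list[Observation]:
    """Read an observation stream from CSV (columns dose_1[..], efficacy, toxicity)."""
    return observations_from_frame(pd.read_csv(path_or_buf))


def observations_to_csv(observations: Sequence[Observation], path_or_buf) -> None:
    observations_to_frame(observations).to_csv(path_or_buf, index=False)
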