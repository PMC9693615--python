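"""Simulation-study engine: replicated adaptive trials and their metrics.

A simulated trial runs the adaptive loop — propose a cohort of trial doses,
sample Bernoulli outcomes from the scenario ground truth, update the
strategy, nominate an interim optimal dose — until the participant budget N
is spent.  Two evaluation metrics are recorded after every cohort:

* *true efficacy/utility at the predicted optimal dose* — the ground-truth
  metric value of the currently nominated dose (dose-selection quality);
* *cumulative sum of efficacy/utility* — accrued participant benefit:
  the count of efficacious responders, or ``n * U(eff_frac, tox_frac)`` of
  the empirical response fractions (trial ethics).

Replicates are aggregated into per-cohort means with 95% confidence
intervals, alongside the theoretical reference lines: the scenario's maximum
and minimum achievable metric, and ``n x max`` / ``n x min`` for the
cumulative metric.  Each replicate draws its random stream from a hash of
(study seed, scenario tag, strategy name, replicate index), so adding
strategies or scenarios never perturbs existing streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ccbp import ExpertPrior, Observation
from .doas import DoseOptimisationStrategy, make_strategy
from .scenarios import Scenario, sample_outcome, scenario_optimum
from .utility import UtilitySpec, utility

__all__ = [
    "TrialConfig",
    "TrialTrajectory",
    "run_trial",
    "cumulative_efficacy",
    "cumulative_utility",
    "true_metric_at",
    "aggregate",
    "run_study",
    "replicate_rng",
    "expert_prior_for",
    "uniform_budget",
]


@dataclass(frozen=True)
class TrialConfig:
    """Trial-simulation settings.

    ``cohort_size`` applies to the adaptive strategies; the Uniform Naive
    strategy overrides it with its domain size and its budget is floored to
    whole cohorts (e.g. 297 of 300 participants on the 9-dose grid).
    """

    n_participants: int = 300
    cohort_size: int = 6
    n_reps: int = 100
    seed: int = 0
    ci_method: str = "t"  # "t" or "bootstrap"

    def __post_init__(self) -> None:
        if not 1 <= self.cohort_size <= self.n_participants:
            raise ValueError("need n_participants >= cohort_size >= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        if self.ci_method not in ("t", "bootstrap"):
            raise ValueError("ci_method must be 't' or 'bootstrap'")


@dataclass
class TrialTrajectory:
    """Per-cohort record of one simulated trial plus its observation log."""

    scenario_tag: str
    strategy_name: str
    cohort: np.ndarray  # 1-based cohort index
    n: np.ndarray  # cumulative participants after the cohort
    predicted_dose: np.ndarray  # (n_cohorts, H) nominated doses
    true_metric: np.ndarray  # ground-truth metric at the nomination
    cumulative_metric: np.ndarray  # cumulative efficacy count or utility
    observations: list[Observation] = field(default_factory=list)


def cumulative_efficacy(log: Sequence[Observation], n: int) -> int:
    """Count of efficacious responders among the first ``n`` participants."""
    if n > len(log):
        raise ValueError(f"only {len(log)} observations logged, asked for {n}")
    return sum(1 for obs in log[:n] if obs.efficacy == 1)


def cumulative_utility(log: Sequence[Observation], n: int, spec: UtilitySpec) -> float:
    """``n * U(eff_frac, tox_frac)`` of the first ``n`` participants (0 at n=0)."""
    if n == 0:
        return 0.0
    if n > len(log):
        raise ValueError(f"only {len(log)} observations logged, asked for {n}")
    n_eff = cumulative_efficacy(log, n)
    n_tox = sum(1 for obs in log[:n] if obs.toxicity == 1)
    return n * utility(n_eff / n, n_tox / n, spec)


def true_metric_at(scenario: Scenario, dose: np.ndarray) -> float:
    """Ground-truth efficacy (or contour utility) at a nominated dose."""
    return float(scenario.utility_at(np.atleast_2d(dose))[0])


def replicate_rng(
    seed: int, scenario_tag: str, strategy_name: str, replicate: int
) -> np.random.Generator:
    """Deterministic, collision-resistant per-replicate random stream."""
    entropy = [
        int(seed) & 0x7FFFFFFF,
        zlib.crc32(scenario_tag.encode()),
        zlib.crc32(strategy_name.encode()),
        int(replicate),
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def run_trial(
    scenario: Scenario,
    strategy: DoseOptimisationStrategy,
    config: TrialConfig,
    rng: np.random.Generator,
) -> TrialTrajectory:
    """Run one adaptive trial of ``strategy`` on ``scenario``.

    Fully deterministic given ``rng``'s state.  The interim optimal dose is
    nominated (and both metrics recorded) after every cohort.
    """
    if strategy.trial_domain.ndim != scenario.domain.ndim:
        raise ValueError("strategy and scenario dimensionality differ")
    if strategy.utility.needs_toxicity and scenario.true_tox is None:
        raise ValueError("strategy needs toxicity but the scenario defines none")

    c = strategy.required_cohort_size or config.cohort_size
    if strategy.required_cohort_size is not None:
        n_cohorts = config.n_participants // c  # whole cohorts only
        sizes = [c] * n_cohorts
    else:
        n_cohorts = -(-config.n_participants // c)
        sizes = [
            min(c, config.n_participants - k * c) for k in range(n_cohorts)
        ]
    if not sizes:
        raise ValueError("participant budget too small for a single cohort")

    log: list[Observation] = []
    cohorts, ns, pred, metric, cum = [], [], [], [], []
    for k, size in enumerate(sizes, start=1):
        idx = strategy.propose_cohort(size, rng)
        batch = [
            sample_outcome(scenario, strategy.trial_domain.doses[i], rng) for i in idx
        ]
        strategy.observe(batch)
        log.extend(batch)

        nominee = strategy.prediction_domain.doses[strategy.nominate(rng)]
        n = len(log)
        cohorts.append(k)
        ns.append(n)
        pred.append(nominee)
        metric.append(true_metric_at(scenario, nominee))
        if scenario.utility.needs_toxicity:
            cum.append(cumulative_utility(log, n, scenario.utility))
        else:
            cum.append(float(cumulative_efficacy(log, n)))

    return TrialTrajectory(
        scenario_tag=scenario.shape_tag,
        strategy_name=strategy.name,
        cohort=np.asarray(cohorts),
        n=np.asarray(ns),
        predicted_dose=np.asarray(pred),
        true_metric=np.asarray(metric),
        cumulative_metric=np.asarray(cum),
        observations=log,
    )


def _mean_ci(
    values: np.ndarray,
    level: float,
    method: str,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column mean and CI of a (reps, cohorts) matrix."""
    mean = values.mean(axis=0)
    n = values.shape[0]
    if n < 2:
        return mean, mean.copy(), mean.copy()
    if method == "t":
        sem = values.std(axis=0, ddof=1) / np.sqrt(n)
        tq = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
        return mean, mean - tq * sem, mean + tq * sem
    # percentile bootstrap of the mean
    rng = rng or np.random.default_rng(0)
    boots = values[rng.integers(0, n, size=(2000, n))].mean(axis=1)
    lo = np.quantile(boots, (1 - level) / 2.0, axis=0)
    hi = np.quantile(boots, 0.5 + level / 2.0, axis=0)
    return mean, lo, hi


def aggregate(
    trajectories: Sequence[TrialTrajectory],
    scenario: Scenario,
    level: float = 0.95,
    method: str = "t",
) -> pd.DataFrame:
    """Per-cohort means and CIs across replicates, with reference lines.

    All trajectories must share one cohort schedule (same ``n`` vector).
    Columns: cohort, n, mean/ci_lo/ci_hi for the true metric and the
    cumulative metric, and the reference lines ref_max, ref_min,
    cum_ref_max, cum_ref_min.
    """
    if len(trajectories) < 1:
        raise ValueError("nothing to aggregate")
    n0 = trajectories[0].n
    if any(not np.array_equal(t.n, n0) for t in trajectories):
        raise ValueError("trajectories have misaligned cohort schedules")

    true_mat = np.vstack([t.true_metric for t in trajectories])
    cum_mat = np.vstack([t.cumulative_metric for t in trajectories])
    t_mean, t_lo, t_hi = _mean_ci(true_mat, level, method)
    c_mean, c_lo, c_hi = _mean_ci(cum_mat, level, method)

    opt = scenario_optimum(scenario)
    return pd.DataFrame(
        {
            "cohort": trajectories[0].cohort,
            "n": n0,
            "true_metric_mean": t_mean,
            "true_metric_ci_lo": t_lo,
            "true_metric_ci_hi": t_hi,
            "cumulative_mean": c_mean,
            "cumulative_ci_lo": c_lo,
            "cumulative_ci_hi": c_hi,
            "ref_max": opt.value,
            "ref_min": opt.min_value,
            "cum_ref_max": n0 * opt.value,
            "cum_ref_min": n0 * opt.min_value,
        }
    )


def expert_prior_for(
    scenario: Scenario,
    domain,
    correct: bool = True,
    confidence: float = 20.0,
) -> dict[str, ExpertPrior]:
    """Expert priors built from the scenario truth, per response channel.

    ``correct=True`` sets the expert prediction to the true response
    probability at every domain dose; ``correct=False`` to one minus it.
    ``confidence`` is the per-dose data-equivalent weight (3 = strong,
    20 = very strong).
    """
    out: dict[str, ExpertPrior] = {}
    p_eff = scenario.eff_at(domain.doses)
    out["efficacy"] = ExpertPrior(
        p_expert=p_eff if correct else 1.0 - p_eff,
        c_expert=np.full(len(domain), float(confidence)),
    )
    p_tox = scenario.tox_at(domain.doses)
    if p_tox is not None:
        out["toxicity"] = ExpertPrior(
            p_expert=p_tox if correct else 1.0 - p_tox,
            c_expert=np.full(len(domain), float(confidence)),
        )
    return out


def uniform_budget(n_participants: int, domain_size: int) -> tuple[int, int]:
    """Whole-cohort budget of the Uniform Naive strategy.

    Returns (number of cohorts, participants actually used); e.g. 300
    participants on a 9-dose grid give 33 cohorts of 9 = 297 used.
    """
    n_cohorts = n_participants // domain_size
    return n_cohorts, n_cohorts * domain_size


def run_study(
    scenarios: Sequence[Scenario],
    strategy_names: Sequence[str],
    config: TrialConfig,
    strategy_kwargs: Optional[dict[str, dict]] = None,
) -> pd.DataFrame:
    """Cartesian product of scenarios x strategies x replicates.

    Returns tidy per-cohort rows: scenario, doa, replicate, cohort, n,
    predicted dose components, true_metric, cumulative_metric.  A failing
    scenario/strategy pairing is recorded (column ``error``) and skipped,
    not fatal to the study.
    """
    strategy_kwargs = strategy_kwargs or {}
    frames: list[pd.DataFrame] = []
    for scenario in scenarios:
        for name in strategy_names:
            try:
                for rep in range(config.n_reps):
                    rng = replicate_rng(config.seed, scenario.shape_tag, name, rep)
                    strategy = make_strategy(
                        name,
                        scenario.domain,
                        scenario.utility,
                        **strategy_kwargs.get(name, {}),
                    )
                    traj = run_trial(scenario, strategy, config, rng)
                    frame = pd.DataFrame(
                        {
                            "scenario": scenario.shape_tag,
                            "doa": name,
                            "replicate": rep,
                            "cohort": traj.cohort,
                            "n": traj.n,
                            "true_metric": traj.true_metric,
                            "cumulative_metric": traj.cumulative_metric,
                        }
                    )
                    for o in range(scenario.domain.ndim):
                        frame[f"predicted_dose_{o + 1}"] = traj.predicted_dose[:, o]
                    frames.append(frame)
            except Exception as exc:  # pairing-level failure: log and continue
                frames.append(
                    pd.DataFrame(
                        {
                            "scenario": [scenario.shape_tag],
                            "doa": [name],
                            "replicate": [-1],
                            "error": [str(exc)],
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)
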