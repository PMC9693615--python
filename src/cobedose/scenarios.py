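"""Synthetic ground-truth scenarios: dose-efficacy and dose-toxicity surfaces.

A scenario is the simulation ground truth: a discretised dosing domain, a
utility specification, a true dose-efficacy curve and (when toxicity is
being traded off) a true dose-toxicity curve.  The catalogue below provides
closed-form curve families covering the qualitative shapes a vaccine
dose-response may take — saturating, peaking, decreasing, undulating,
flattened-peaking in one administration; synergistic/antagonistic
compositions over prime/boost (and second-boost) administrations; gradually
or sharply increasing toxicity.

Curve families (dose components pre-scaled to [0, 1]):

* saturating — Emax/Hill: ``p(d) = p_min + (p_max - p_min) d^h / (d^h + d50^h)``
* peaking — Gaussian bump: ``p(d) = p_min + (p_max - p_min) exp(-(d - peak)^2 / w^2)``
* flattened peaking — quartic-exponent bump, giving a plateau around the peak
* decreasing — reversed saturating (maximal at the smallest dose)
* undulating — bounded linear trend plus one sinusoidal term (multimodal)
* multi-dose — additive per-axis Hill/bump latents with optional interaction
  terms, normalised so probabilities stay inside [0, 1]

Every constructor validates that its output lies in [0, 1] across the dense
grid, and each carries a shape assertion used by the test-suite (monotone /
interior peak / multimodal / plateau / corner properties).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .ccbp import Observation
from .kernels import DosingDomain
from .utility import UtilitySpec, utility_vector

__all__ = [
    "Scenario",
    "make_scenario",
    "sample_outcome",
    "scenario_optimum",
    "EFFICACY_TAGS",
    "TOXICITY_TAGS",
]

CurveFn = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class Scenario:
    """Ground truth for a simulated trial.

    ``true_eff`` / ``true_tox`` map an (n, H) array of doses to probability
    vectors; they are defined continuously, so fine and coarse grids share
    one truth.  ``true_tox`` is present iff the utility is the contour.
    """

    domain: DosingDomain
    utility: UtilitySpec
    true_eff: CurveFn
    true_tox: Optional[CurveFn]
    shape_tag: str

    def __post_init__(self) -> None:
        if self.utility.needs_toxicity and self.true_tox is None:
            raise ValueError("utility_contour scenarios require a toxicity curve")
        if not self.utility.needs_toxicity and self.true_tox is not None:
            raise ValueError("toxicity curve supplied but the utility ignores it")

    def eff_at(self, doses: np.ndarray) -> np.ndarray:
        return self.true_eff(np.atleast_2d(doses))

    def tox_at(self, doses: np.ndarray) -> Optional[np.ndarray]:
        if self.true_tox is None:
            return None
        return self.true_tox(np.atleast_2d(doses))

    def utility_at(self, doses: np.ndarray) -> np.ndarray:
        """True utility (efficacy, or contour of efficacy and toxicity)."""
        doses = np.atleast_2d(doses)
        return utility_vector(self.eff_at(doses), self.tox_at(doses), self.utility)

    def to_frame(self) -> pd.DataFrame:
        """Export the ground truth over the domain as a table."""
        cols = {
            f"dose_{o + 1}": self.domain.doses[:, o] for o in range(self.domain.ndim)
        }
        cols["true_eff"] = self.eff_at(self.domain.doses)
        tox = self.tox_at(self.domain.doses)
        if tox is not None:
            cols["true_tox"] = tox
        cols["true_utility"] = self.utility_at(self.domain.doses)
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# 1-D building blocks


def _hill(d: np.ndarray, d50: float, h: float) -> np.ndarray:
    # normalised so the latent attains exactly 1 at the top of the axis
    d = np.asarray(d, dtype=float)
    return (d**h / (d**h + d50**h)) * (1.0 + d50**h)


def _bump(d: np.ndarray, peak: float, width: float, power: float = 2.0) -> np.ndarray:
    return np.exp(-(np.abs(np.asarray(d, dtype=float) - peak) / width) ** power)


def _scaled(f01: Callable[[np.ndarray], np.ndarray], p_min: float, p_max: float) -> CurveFn:
    def curve(doses: np.ndarray) -> np.ndarray:
        return p_min + (p_max - p_min) * f01(np.atleast_2d(doses))

    return curve


# ---------------------------------------------------------------------------
# catalogue constructors: tag -> (ndim, default params, latent in [0, 1])


def _eff_1d(fn: Callable[[np.ndarray], np.ndarray]) -> Callable[[np.ndarray], np.ndarray]:
    return lambda doses: fn(doses[:, 0])


_EFFICACY: dict[str, tuple[int, dict, Callable[[dict], Callable[[np.ndarray], np.ndarray]]]] = {
    # --- single administration -------------------------------------------
    "gently_saturating": (
        1,
        dict(p_min=0.1, p_max=0.9, d50=0.35, hill=1.5),
        lambda p: _eff_1d(lambda d: _hill(d, p["d50"], p["hill"])),
    ),
    "sharply_saturating": (
        1,
        dict(p_min=0.05, p_max=0.9, d50=0.25, hill=6.0),
        lambda p: _eff_1d(lambda d: _hill(d, p["d50"], p["hill"])),
    ),
    "gently_peaking": (
        1,
        dict(p_min=0.1, p_max=0.8, peak=0.55, width=0.35),
        lambda p: _eff_1d(lambda d: _bump(d, p["peak"], p["width"])),
    ),
    "sharply_peaking": (
        1,
        dict(p_min=0.05, p_max=0.9, peak=0.5, width=0.1),
        lambda p: _eff_1d(lambda d: _bump(d, p["peak"], p["width"])),
    ),
    "decreasing": (
        1,
        dict(p_min=0.1, p_max=0.85, d50=0.4, hill=2.0),
        lambda p: _eff_1d(lambda d: 1.0 - _hill(d, p["d50"], p["hill"])),
    ),
    "undulating": (
        1,
        dict(p_min=0.15, p_max=0.85, trend=0.3, wobble=0.35, cycles=1.5),
        lambda p: _eff_1d(
            lambda d: (
                (1.0 - p["trend"] - p["wobble"]) / 2.0
                + p["trend"] * d
                + p["wobble"] * (0.5 + 0.5 * np.sin(2.0 * np.pi * p["cycles"] * d))
            )
        ),
    ),
    "flattened_peaking": (
        1,
        dict(p_min=0.3, p_max=0.45, peak=0.5, width=0.35),
        lambda p: _eff_1d(lambda d: _bump(d, p["peak"], p["width"], power=4.0)),
    ),
    # --- prime/boost ------------------------------------------------------
    "synergistic_peaking": (
        2,
        dict(p_min=0.05, p_max=0.9, peak=(0.5, 0.5), width=0.45),
        lambda p: lambda doses: _bump(
            np.sqrt(
                (doses[:, 0] - p["peak"][0]) ** 2 + (doses[:, 1] - p["peak"][1]) ** 2
            ),
            0.0,
            p["width"],
        ),
    ),
    "antagonistic_saturating": (
        2,
        dict(p_min=0.05, p_max=0.9, d50=0.3, hill=3.0, antagonism=1.5),
        lambda p: lambda doses: (
            _hill(doses[:, 0], p["d50"], p["hill"])
            + _hill(doses[:, 1], p["d50"], p["hill"])
            - p["antagonism"]
            * _hill(doses[:, 0], p["d50"], p["hill"])
            * _hill(doses[:, 1], p["d50"], p["hill"])
        ),
    ),
    "synergistic_saturating": (
        2,
        dict(p_min=0.05, p_max=0.9, d50=0.35, hill=2.0, synergy=1.0),
        lambda p: lambda doses: (
            _hill(doses[:, 0], p["d50"], p["hill"])
            + _hill(doses[:, 1], p["d50"], p["hill"])
            + p["synergy"]
            * _hill(doses[:, 0], p["d50"], p["hill"])
            * _hill(doses[:, 1], p["d50"], p["hill"])
        )
        / (2.0 + p["synergy"]),
    ),
    "saturating_with_high_dose_decline": (
        2,
        dict(p_min=0.05, p_max=0.9, d50=0.3, hill=3.0, decline=0.6, decline_width=0.15),
        lambda p: lambda doses: (
            (
                _hill(doses[:, 0], p["d50"], p["hill"])
                + _hill(doses[:, 1], p["d50"], p["hill"])
                + _hill(doses[:, 0], p["d50"], p["hill"])
                * _hill(doses[:, 1], p["d50"], p["hill"])
            )
            / 3.0
            * (
                1.0
                - p["decline"]
                * np.exp(
                    -((doses[:, 0] - 1.0) ** 2 + (doses[:, 1] - 1.0) ** 2)
                    / p["decline_width"]
                )
            )
        ),
    ),
    "one_dose_dominant": (
        2,
        dict(p_min=0.05, p_max=0.9, d50=0.3, hill=2.5, dominance=0.85),
        lambda p: lambda doses: (
            p["dominance"] * _hill(doses[:, 0], p["d50"], p["hill"])
            + (1.0 - p["dominance"]) * _hill(doses[:, 1], p["d50"], p["hill"])
        ),
    ),
    # --- prime/boost/second-boost ----------------------------------------
    "independent_peaking": (
        3,
        dict(p_min=0.05, p_max=0.9, peaks=(0.3, 0.5, 0.7), width=0.45),
        lambda p: lambda doses: np.exp(
            -sum(
                (doses[:, o] - p["peaks"][o]) ** 2 / p["width"] ** 2
                for o in range(3)
            )
        ),
    ),
    "two_of_three_maximal": (
        3,
        dict(p_min=0.05, p_max=0.9, target_total=2.0, width=0.6),
        lambda p: lambda doses: np.exp(
            -((doses.sum(axis=1) - p["target_total"]) ** 2) / p["width"] ** 2
        ),
    ),
}

_TOXICITY: dict[str, tuple[int, dict, Callable[[dict], Callable[[np.ndarray], np.ndarray]]]] = {
    "gradually_increasing": (
        1,
        dict(t_min=0.02, t_max=0.5, power=1.2),
        lambda p: _eff_1d(lambda d: d ** p["power"]),
    ),
    "sharply_increasing": (
        1,
        dict(t_min=0.02, t_max=0.7, d50=0.7, hill=8.0),
        lambda p: _eff_1d(lambda d: _hill(d, p["d50"], p["hill"])),
    ),
    "increasing_in_either_dose": (
        2,
        dict(t_min=0.02, t_max=0.6, power=2.0),
        lambda p: lambda doses: 1.0
        - (1.0 - doses[:, 0] ** p["power"]) * (1.0 - doses[:, 1] ** p["power"]),
    ),
}

EFFICACY_TAGS = tuple(_EFFICACY)
TOXICITY_TAGS = tuple(_TOXICITY)

#: Fine-grid resolution per dimensionality used by the modelling strategies.
FINE_GRID_POINTS = {1: 101, 2: 21, 3: 11}
#: Coarse-grid resolution per dimensionality used by the naive strategies.
COARSE_GRID_POINTS = {1: 6, 2: 3, 3: 3}


def _build_curve(
    tag: str,
    table: dict,
    params: Optional[dict],
    lo_key: str,
    hi_key: str,
) -> tuple[int, CurveFn]:
    if tag not in table:
        raise KeyError(f"unknown shape tag {tag!r}; known: {sorted(table)}")
    ndim, defaults, factory = table[tag]
    p = dict(defaults)
    if params:
        unknown = set(params) - set(defaults)
        if unknown:
            raise KeyError(f"unknown parameters for {tag!r}: {sorted(unknown)}")
        p.update(params)
    latent = factory(p)
    curve = _scaled(latent, p[lo_key], p[hi_key])

    # reject parameterisations that escape [0, 1] anywhere on a dense grid
    probe = DosingDomain.regular_grid(FINE_GRID_POINTS[ndim], ndim).doses
    vals = curve(probe)
    if np.any(vals < -1e-12) or np.any(vals > 1.0 + 1e-12):
        raise ValueError(
            f"{tag!r} with params {p} produces probabilities outside [0, 1] "
            f"(range {vals.min():.4f}..{vals.max():.4f})"
        )
    return ndim, curve


def make_scenario(
    shape_tag: str,
    domain: Optional[DosingDomain] = None,
    utility: Optional[UtilitySpec] = None,
    params: Optional[dict] = None,
    tox_tag: Optional[str] = None,
    tox_params: Optional[dict] = None,
) -> Scenario:
    """Construct a catalogue scenario.

    Parameters
    ----------
    shape_tag
        Efficacy-curve tag from :data:`EFFICACY_TAGS`.
    domain
        Dosing domain; defaults to the fine grid for the tag's dimensionality
        (101 doses in 1-D, 21x21 in 2-D, 11x11x11 in 3-D).
    utility
        Defaults to maximum-efficacy without a toxicity tag, or the default
        utility contour with one.
    params, tox_params
        Overrides for the curve-family defaults.
    tox_tag
        Optional toxicity-curve tag from :data:`TOXICITY_TAGS`; providing one
        makes this a contour (efficacy/toxicity trade-off) scenario.
    """
    ndim, eff = _build_curve(shape_tag, _EFFICACY, params, "p_min", "p_max")

    tox: Optional[CurveFn] = None
    tag = shape_tag
    if tox_tag is not None:
        tox_ndim, tox = _build_curve(tox_tag, _TOXICITY, tox_params, "t_min", "t_max")
        if tox_ndim != ndim:
            raise ValueError("efficacy and toxicity tags have different dimensionality")
        tag = f"{shape_tag}+{tox_tag}"
        if utility is None:
            utility = UtilitySpec.contour()
    elif utility is None:
        utility = UtilitySpec.maximum_efficacy()

    if domain is None:
        domain = DosingDomain.regular_grid(FINE_GRID_POINTS[ndim], ndim)
    if domain.ndim != ndim:
        raise ValueError(
            f"domain dimensionality {domain.ndim} does not match tag {shape_tag!r} ({ndim})"
        )
    return Scenario(domain=domain, utility=utility, true_eff=eff, true_tox=tox, shape_tag=tag)


def sample_outcome(
    scenario: Scenario, dose: np.ndarray, rng: np.random.Generator
) -> Observation:
    """Simulate one participant at ``dose``: independent Bernoulli outcomes."""
    dose = np.atleast_1d(np.asarray(dose, dtype=float))
    p_eff = float(scenario.eff_at(dose)[0])
    efficacy = int(rng.random() < p_eff)
    toxicity = None
    if scenario.true_tox is not None:
        p_tox = float(scenario.tox_at(dose)[0])
        toxicity = int(rng.random() < p_tox)
    return Observation(dose=tuple(dose), efficacy=efficacy, toxicity=toxicity)


@dataclass(frozen=True)
class ScenarioOptimum:
    """Exhaustive-scan optimum of the true metric over the domain."""

    dose: tuple[float, ...]
    value: float
    min_value: float


def scenario_optimum(scenario: Scenario) -> ScenarioOptimum:
    """Scan the true utility (or efficacy) over the domain; argmax, max, min.

    The max bounds every strategy's achievable true metric; max and min are
    the upper and lower reference lines of the evaluation plots.
    """
    vals = scenario.utility_at(scenario.domain.doses)
    best = int(np.argmax(vals))
    return ScenarioOptimum(
        dose=tuple(scenario.domain.doses[best]),
        value=float(vals[best]),
        min_value=float(vals.min()),
    )
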