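"""Utility functions mapping (p_eff, p_tox) to a scalar to maximise.

Two utilities are supported.  *Maximum efficacy* is simply U = p_eff.  The
*utility contour* balances efficacy against toxicity:

    U = 1 - [ ((1 - p_eff) / (1 - anchor_eff))^rho + (p_tox / anchor_tox)^rho ]^(1/rho)

Its zero-utility level set passes exactly through the clinician-specified
anchor points (anchor_eff, 0) and (1, anchor_tox); rho controls the
curvature of the trade-off.  Values below zero (worse than the zero-utility
contour) are legal and ranked as such — the utility is never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["UtilitySpec", "utility", "utility_vector"]

#: Illustrative contour defaults (EffTox-style); not tied to any dataset.
DEFAULT_ANCHOR_EFF = 0.5
DEFAULT_ANCHOR_TOX = 0.65
DEFAULT_RHO = 2.0


@dataclass(frozen=True)
class UtilitySpec:
    """Choice of utility: ``maximum_efficacy`` or ``utility_contour``.

    Contour parameters are required (and validated) only for the contour
    kind; anchors must lie strictly inside (0, 1) and rho must be positive.
    """

    kind: str
    anchor_eff: Optional[float] = None
    anchor_tox: Optional[float] = None
    rho: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("maximum_efficacy", "utility_contour"):
            raise ValueError(f"unknown utility kind {self.kind!r}")
        if self.kind == "utility_contour":
            if self.anchor_eff is None or self.anchor_tox is None or self.rho is None:
                raise ValueError("utility_contour requires anchor_eff, anchor_tox and rho")
            if not (0.0 < self.anchor_eff < 1.0 and 0.0 < self.anchor_tox < 1.0):
                raise ValueError("anchors must lie strictly inside (0, 1)")
            if self.rho <= 0:
                raise ValueError("rho must be positive")
        elif any(v is not None for v in (self.anchor_eff, self.anchor_tox, self.rho)):
            raise ValueError("contour parameters are only valid for utility_contour")

    @property
    def needs_toxicity(self) -> bool:
        return self.kind == "utility_contour"

    @classmethod
    def maximum_efficacy(cls) -> "UtilitySpec":
        return cls(kind="maximum_efficacy")

    @classmethod
    def contour(
        cls,
        anchor_eff: float = DEFAULT_ANCHOR_EFF,
        anchor_tox: float = DEFAULT_ANCHOR_TOX,
        rho: float = DEFAULT_RHO,
    ) -> "UtilitySpec":
        return cls(kind="utility_contour", anchor_eff=anchor_eff, anchor_tox=anchor_tox, rho=rho)


def _validate_probs(p: np.ndarray, name: str) -> None:
    if np.any((p < 0) | (p > 1)):
        raise ValueError(f"{name} must lie in [0, 1]")


def utility(p_eff: float, p_tox: float | None, spec: UtilitySpec) -> float:
    """Scalar utility of an (efficacy, toxicity) probability pair."""
    p_tox_val = 0.0 if p_tox is None else p_tox
    return float(utility_vector(np.atleast_1d(p_eff), np.atleast_1d(p_tox_val), spec)[0])


def utility_vector(
    p_eff: np.ndarray, p_tox: np.ndarray | None, spec: UtilitySpec
) -> np.ndarray:
    """Elementwise utility over per-dose probability vectors."""
    p_eff = np.asarray(p_eff, dtype=float)
    _validate_probs(p_eff, "p_eff")
    if spec.kind == "maximum_efficacy":
        return p_eff.copy()
    if p_tox is None:
        raise ValueError("utility_contour requires toxicity probabilities")
    p_tox = np.asarray(p_tox, dtype=float)
    if p_tox.shape != p_eff.shape:
        raise ValueError("p_eff and p_tox must have equal length")
    _validate_probs(p_tox, "p_tox")
    eff_term = ((1.0 - p_eff) / (1.0 - spec.anchor_eff)) ** spec.rho
    tox_term = (p_tox / spec.anchor_tox) ** spec.rho
    return 1.0 - (eff_term + tox_term) ** (1.0 / spec.rho)
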