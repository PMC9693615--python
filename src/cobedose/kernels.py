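"""Dose-similarity kernels for the Continuous Correlated Beta Process.

Doses are vectors of 1–3 components (single administration, prime/boost,
prime/boost/second-boost), each component pre-scaled to [0, 1].  Similarity
between doses controls how strongly an observation at one dose informs the
beta posterior at every other dose.  The kernel used throughout is the
squared-exponential

    K(d_i, d_j) = exp(-sum_o (d_io - d_jo)^2 / l_o^2),

with one positive length hyperparameter ``l_o`` per administration axis.  It
is symmetric, equals 1 exactly when the doses coincide, is strictly positive
for any finite separation, and factorises across axes into a product of
one-dimensional kernels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KernelSpec",
    "DosingDomain",
    "sq_exp_kernel",
    "kernel_row",
    "DEFAULT_LENGTHS",
]

#: Default kernel lengths by dosing-domain dimensionality: 0.2 for a single
#: administration, 0.25 per axis for prime/boost, 0.4 per axis for
#: prime/boost/second-boost.
DEFAULT_LENGTHS: dict[int, tuple[float, ...]] = {
    1: (0.2,),
    2: (0.25, 0.25),
    3: (0.4, 0.4, 0.4),
}


def _as_dose(dose: Sequence[float] | float) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(dose, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"a dose must be a 1-D vector, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class KernelSpec:
    """Squared-exponential kernel hyperparameters, one length per dose axis.

    Lengths need not be equal across axes; equal lengths are merely the
    common choice.
    """

    lengths: tuple[float, ...]

    def __post_init__(self) -> None:
        lengths = tuple(float(l) for l in self.lengths)
        if len(lengths) not in (1, 2, 3):
            raise ValueError("kernel must have 1, 2 or 3 length parameters")
        if any(l <= 0 or not np.isfinite(l) for l in lengths):
            raise ValueError(f"kernel lengths must be positive finite, got {lengths}")
        object.__setattr__(self, "lengths", lengths)

    @property
    def ndim(self) -> int:
        return len(self.lengths)

    @classmethod
    def default(cls, ndim: int) -> "KernelSpec":
        """The default lengths for an ``ndim``-administration domain."""
        return cls(DEFAULT_LENGTHS[ndim])


class DosingDomain:
    """An ordered, finite set of candidate doses sharing one dimensionality.

    The domain order is stable and indexes every per-dose quantity held by
    models and strategies (beta parameters, medians, utilities).

    Parameters
    ----------
    doses
        Sequence of dose vectors, each of the same length H in {1, 2, 3},
        every component in [0, 1], no duplicates.
    """

    def __init__(self, doses: Iterable[Sequence[float] | float]):
        arr = np.asarray([_as_dose(d) for d in doses], dtype=float)
        if arr.size == 0:
            raise ValueError("dosing domain must contain at least one dose")
        if arr.ndim != 2 or arr.shape[1] not in (1, 2, 3):
            raise ValueError("doses must share a dimensionality H in {1, 2, 3}")
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("all dose components must lie in [0, 1]")
        if len(np.unique(arr, axis=0)) != len(arr):
            raise ValueError("dosing domain contains duplicate doses")
        self.doses: np.ndarray = arr
        self.doses.setflags(write=False)

    @property
    def ndim(self) -> int:
        """Number of administrations H per dose."""
        return self.doses.shape[1]

    @property
    def n_doses(self) -> int:
        return self.doses.shape[0]

    def __len__(self) -> int:
        return self.n_doses

    def __getitem__(self, i: int) -> np.ndarray:
        return self.doses[i]

    def __repr__(self) -> str:
        return f"DosingDomain(n_doses={self.n_doses}, ndim={self.ndim})"

    def index_of(self, dose: Sequence[float] | float) -> int:
        """Exact index of ``dose`` in the domain; raises if absent."""
        d = _as_dose(dose)
        if d.shape[0] != self.ndim:
            raise ValueError("dose dimensionality does not match the domain")
        hits = np.flatnonzero(np.all(self.doses == d, axis=1))
        if hits.size == 0:
            raise ValueError(f"dose {tuple(d)} is not a member of the domain")
        return int(hits[0])

    @classmethod
    def regular_grid(cls, points_per_axis: int, ndim: int = 1) -> "DosingDomain":
        """Evenly spaced grid on [0, 1]^ndim with ``points_per_axis`` per axis.

        ``regular_grid(101, 1)`` is the fine single-administration domain,
        ``regular_grid(21, 2)`` the 441-dose prime/boost grid,
        ``regular_grid(11, 3)`` the 1331-dose triple grid and
        ``regular_grid(6, 1)`` / ``regular_grid(3, 2)`` / ``regular_grid(3, 3)``
        the coarse 6 / 9 / 27-dose domains of the naive strategies.
        """
        if points_per_axis < 2:
            raise ValueError("need at least 2 points per axis")
        axis = np.linspace(0.0, 1.0, points_per_axis)
        grids = np.meshgrid(*([axis] * ndim), indexing="ij")
        doses = np.column_stack([g.ravel() for g in grids])
        return cls(doses)


def _check_dims(d_i: np.ndarray, d_j: np.ndarray, spec: KernelSpec) -> None:
    if not (d_i.shape[0] == d_j.shape[0] == spec.ndim):
        raise ValueError(
            "dimensionality mismatch: doses have "
            f"{d_i.shape[0]} and {d_j.shape[0]} components, kernel has "
            f"{spec.ndim} lengths"
        )


def sq_exp_kernel(
    d_i: Sequence[float] | float,
    d_j: Sequence[float] | float,
    spec: KernelSpec,
) -> float:
    """Squared-exponential similarity between two doses, in (0, 1].

    Returns ``exp(-sum_o (d_io - d_jo)^2 / l_o^2)``.  Equals 1 iff the doses
    are identical; decays towards (but never reaches, at finite separation)
    0 as they move apart.
    """
    a, b = _as_dose(d_i), _as_dose(d_j)
    _check_dims(a, b, spec)
    z = (a - b) / np.asarray(spec.lengths)
    return float(np.exp(-np.dot(z, z)))


def kernel_row(
    d_j: Sequence[float] | float,
    domain: DosingDomain,
    spec: KernelSpec,
) -> np.ndarray:
    """Similarity of ``d_j`` to every dose in ``domain`` (vectorised).

    ``d_j`` need not itself belong to the domain; the kernel is defined
    continuously.  Element k equals ``sq_exp_kernel(domain[k], d_j, spec)``,
    and is exactly 1 wherever a domain dose coincides with ``d_j``.
    """
    d = _as_dose(d_j)
    if d.shape[0] != domain.ndim or spec.ndim != domain.ndim:
        raise ValueError("dose / kernel dimensionality does not match the domain")
    z = (domain.doses - d) / np.asarray(spec.lengths)
    row = np.exp(-np.sum(z * z, axis=1))
    # exact self-similarity where the dose is a member of the grid
    row[np.all(domain.doses == d, axis=1)] = 1.0
    return row
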