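"""Normalized Legendre bases and covariance functions over hen age.

Random-regression models describe each hen's deviation from the fixed
lay-cycle curve as a low-order polynomial of standardized age.  The
basis used throughout is the normalized Legendre basis
phi_j(t) = sqrt((2j+1)/2) * P_j(t), orthonormal on [-1, 1], with ages
(weeks) mapped linearly onto [-1, 1].  A random term with coefficient
covariance K then induces the covariance function
Sigma(t, t') = phi(t)' K phi(t') over ages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = [
    "AgeGrid",
    "standardize_age",
    "legendre_row",
    "basis_matrix",
    "covariance_function",
]


@dataclass(frozen=True)
class AgeGrid:
    """Ordered integer ages (weeks) with standardization bounds."""

    ages: tuple
    a_min: float
    a_max: float

    def __post_init__(self):
        if not self.a_min < self.a_max:
            raise ValueError("a_min must be < a_max")
        ages = tuple(self.ages)
        if any(a < self.a_min or a > self.a_max for a in ages):
            raise ValueError("all ages must lie within [a_min, a_max]")
        if list(ages) != sorted(ages):
            raise ValueError("ages must be ordered")
        object.__setattr__(self, "ages", ages)

    @classmethod
    def weekly(cls, a_min: int = 27, a_max: int = 58) -> "AgeGrid":
        """One grid point per week over the laying period (default 27-58 wk)."""
        return cls(tuple(range(a_min, a_max + 1)), a_min, a_max)

    @property
    def n(self) -> int:
        return len(self.ages)


def standardize_age(age, a_min: float, a_max: float):
    """Map age in weeks to t in [-1, 1]: t = -1 + 2(age - a_min)/(a_max - a_min).

    No extrapolation: ages outside [a_min, a_max] raise ValueError.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < a_min) or np.any(age > a_max):
        raise ValueError(f"age outside standardization bounds [{a_min}, {a_max}]")
    t = -1.0 + 2.0 * (age - a_min) / (a_max - a_min)
    return t if t.ndim else float(t)


def legendre_row(t, order: int) -> np.ndarray:
    """Normalized Legendre values phi_0(t)..phi_order(t).

    phi_j(t) = sqrt((2j+1)/2) * P_j(t); the factor makes the basis
    orthonormal on [-1, 1], so K entries are interpretable as
    (co)variances of comparable magnitude across orders.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    t = np.asarray(t, dtype=float)
    V = npleg.legvander(t, order)
    scale = np.sqrt((2.0 * np.arange(order + 1) + 1.0) / 2.0)
    out = V * scale
    return out[0] if t.ndim == 0 else out


def basis_matrix(grid: AgeGrid, order: int) -> np.ndarray:
    """Basis matrix Phi (n_ages x order+1): row per age of the grid."""
    t = standardize_age(np.asarray(grid.ages, dtype=float), grid.a_min, grid.a_max)
    return legendre_row(np.atleast_1d(t), order)


def covariance_function(K: np.ndarray, grid: AgeGrid, order: int) -> np.ndarray:
    """Per-age covariance matrix Sigma = Phi K Phi' of a random-regression term.

    Sigma[i, i] is the term's variance at grid age i.
    """
    K = np.asarray(K, dtype=float)
    if K.shape != (order + 1, order + 1):
        raise ValueError(
            f"K has shape {K.shape}, expected {(order + 1, order + 1)} for order {order}"
        )
    Phi = basis_matrix(grid, order)
    S = Phi @ K @ Phi.T
    return 0.5 * (S + S.T)
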