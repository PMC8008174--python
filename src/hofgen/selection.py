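"""Response to selection and the multitrait selection index.

Annualized genetic gain under truncation selection:

    R = i r sigma_a / L                       (single record per animal)
    R = i r sigma_a sqrt(n / (1 + (n-1) re)) / L   (n repeated records)

with i the selection intensity, r the selection accuracy, sigma_a the
additive genetic standard deviation, re the repeatability and L the
generation interval in years.  For the multitrait case the Hazel/Smith
index b = P^-1 G a gives Var(I) = b' P b and R = i sqrt(Var(I)) / L.
The square-root form of the repeated-records multiplier is the standard
accuracy of a mean of n records; the printed non-root variant is
available behind ``sqrt_multiplier=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["SelectionInputs", "IndexInputs", "selection_intensity",
           "response_single", "response_repeated", "index_weights",
           "response_index", "accuracy_from_pev", "model_comparison_report"]


@dataclass(frozen=True)
class SelectionInputs:
    """Ingredients of single-trait annualized response."""

    i: float                  # selection intensity (SD units)
    r: float                  # selection accuracy
    sigma_a: float            # additive genetic SD, trait units
    L: float = 1.0            # generation interval, years
    n: float = 1.0            # mean records per animal
    re: float = 0.0           # repeatability

    def __post_init__(self):
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("accuracy r must be in [0, 1]")
        if not 0.0 <= self.re <= 1.0:
            raise ValueError("repeatability re must be in [0, 1]")
        if self.n < 1:
            raise ValueError("mean records per animal n must be >= 1")
        if self.L <= 0:
            raise ValueError("generation interval L must be positive")


@dataclass(frozen=True)
class IndexInputs:
    """Phenotypic/genetic covariances and economic weights for the index."""

    P: np.ndarray
    G: np.ndarray
    a: np.ndarray

    def __post_init__(self):
        P = np.atleast_2d(np.asarray(self.P, dtype=float))
        G = np.atleast_2d(np.asarray(self.G, dtype=float))
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        if P.shape != G.shape or P.shape[0] != len(a):
            raise ValueError("P, G and a dimensions disagree")
        if not (np.allclose(P, P.T) and np.allclose(G, G.T)):
            raise ValueError("P and G must be symmetric")
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "a", a)


def selection_intensity(proportion: float) -> float:
    """Mean deviation (SD units) of the selected fraction under truncation.

    i = z / p with z the standard normal density at the truncation
    point Phi^-1(1 - p).
    """
    if not 0.0 < proportion < 1.0:
        raise ValueError("selected proportion must be strictly inside (0, 1)")
    x = norm.ppf(1.0 - proportion)
    return float(norm.pdf(x) / proportion)


def response_single(si: SelectionInputs) -> float:
    """Annual response R = i r sigma_a / L (one record per animal)."""
    return si.i * si.r * si.sigma_a / si.L


def response_repeated(si: SelectionInputs, sqrt_multiplier: bool = True) -> float:
    """Annual response with n repeated records of repeatability re.

    Multiplies the single-record response by sqrt(n / (1 + (n-1) re))
    (the accuracy gain of a mean of n records); ``sqrt_multiplier=False``
    applies the multiplier without the square root.
    """
    m = si.n / (1.0 + (si.n - 1.0) * si.re)
    mult = np.sqrt(m) if sqrt_multiplier else m
    return response_single(si) * float(mult)


def index_weights(ix: IndexInputs) -> np.ndarray:
    """Smith-Hazel index weights b = P^-1 G a."""
    try:
        return np.linalg.solve(ix.P, ix.G @ ix.a)
    except np.linalg.LinAlgError as err:
        raise ValueError("phenotypic covariance matrix P is singular") from err


def response_index(ix: IndexInputs, i: float, L: float = 1.0) -> tuple:
    """Annual index response and index variance.

    Var(I) = b' P b; R = i sqrt(Var(I)) / L (response per standardized
    selection differential is the index standard deviation).
    """
    b = index_weights(ix)
    var_I = float(b @ ix.P @ b)
    return i * np.sqrt(max(var_I, 0.0)) / L, var_I


def accuracy_from_pev(pev: np.ndarray, sigma2_a: float,
                      inbreeding: np.ndarray | None = None) -> np.ndarray:
    """Per-animal BLUP accuracy r = sqrt(1 - PEV / ((1 + F) sigma2_a))."""
    denom = sigma2_a * (1.0 + (inbreeding if inbreeding is not None else 0.0))
    r2 = np.clip(1.0 - np.asarray(pev, dtype=float) / denom, 0.0, 1.0)
    return np.sqrt(r2)


def model_comparison_report(responses: dict, phenotypic_mean: float) -> pd.DataFrame:
    """Annual gain per model and its size relative to the trait mean.

    ``responses`` maps a model label to its annual genetic gain; the
    percent column is 100 * gain / phenotypic mean.
    """
    rows = [
        {"model": m, "gain_per_year": r,
         "pct_of_mean": 100.0 * r / phenotypic_mean}
        for m, r in responses.items()
    ]
    return pd.DataFrame(rows, columns=["model", "gain_per_year", "pct_of_mean"])
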