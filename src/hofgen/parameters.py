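"""Heritabilities, repeatability, parameter surfaces and scale transforms.

Fitted variance components are turned into the quantities breeders
actually compare across models: scalar heritability and repeatability
for the cumulative/repeatability/fixed-regression models, per-age
variance and heritability trajectories plus age x age correlation
matrices for the random regression model, and the liability-to-observed
scale transform for the threshold model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .components import VarianceComponents
from .legendre import AgeGrid, basis_matrix

__all__ = ["ParameterSurface", "heritability_scalar", "rrm_surface",
           "liability_to_observed"]


@dataclass
class ParameterSurface:
    """Per-age genetic parameters from a random regression fit."""

    grid: AgeGrid
    var_a: np.ndarray
    var_pef: np.ndarray
    var_pem: np.ndarray
    var_e: np.ndarray
    h2: np.ndarray
    corr_g: np.ndarray    # age x age genetic correlations
    corr_p: np.ndarray    # age x age phenotypic correlations

    @property
    def h2_average(self) -> float:
        """Unweighted mean of per-age heritability over the grid."""
        return float(np.mean(self.h2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age_week": self.grid.ages,
            "var_a": self.var_a,
            "var_pef": self.var_pef,
            "var_pem": self.var_pem,
            "var_e": self.var_e,
            "h2": self.h2,
        })


def heritability_scalar(vc: VarianceComponents) -> tuple:
    """Heritability and repeatability from scalar variance components.

    h2 = sigma2_a / sigma2_P with sigma2_P the sum of all fitted
    components (the mate permanent environment counts as part of the
    hen-week record's variance); repeatability re adds both permanent
    environment terms to the numerator.  For the cumulative model (no
    permanent environment) re equals h2.
    """
    s_a = vc.scalar("aF")
    s_pf = vc.scalar("peF") if "peF" in vc.terms else 0.0
    s_pm = vc.scalar("peM") if "peM" in vc.terms else 0.0
    s_e = vc.sigma2_e
    s_p = s_a + s_pf + s_pm + s_e
    if s_p <= 0:
        raise ValueError("total phenotypic variance is zero")
    return s_a / s_p, (s_a + s_pf + s_pm) / s_p


def rrm_surface(vc: VarianceComponents, grid: AgeGrid,
                genetic_order: int = 2, pe_order: int = 3) -> ParameterSurface:
    """Per-age variances, heritability and correlations from RRM components.

    The residual is independent across weeks, so it contributes only to
    the diagonal of the phenotypic covariance.  Correlations at an age
    with zero variance are reported as NaN.
    """
    Phi_a = basis_matrix(grid, genetic_order)
    Phi_p = basis_matrix(grid, pe_order)
    cov_a = Phi_a @ vc.K("aF") @ Phi_a.T
    cov_pf = Phi_p @ vc.K("peF") @ Phi_p.T
    cov_pm = Phi_p @ vc.K("peM") @ Phi_p.T
    var_a = np.diag(cov_a).copy()
    var_pf = np.diag(cov_pf).copy()
    var_pm = np.diag(cov_pm).copy()
    res = vc.residual
    if res is None:
        var_e = np.zeros(grid.n)
    elif len(res) == 1:
        var_e = np.full(grid.n, res[0])
    elif len(res) == grid.n:
        var_e = np.asarray(res, dtype=float)
    else:
        raise ValueError(
            f"residual has {len(res)} classes, expected 1 or {grid.n} (one per week)"
        )
    var_p = var_a + var_pf + var_pm + var_e
    h2 = np.where(var_p > 0, var_a / np.where(var_p > 0, var_p, 1.0), np.nan)
    cov_p = cov_a + cov_pf + cov_pm + np.diag(var_e)
    corr_g = _to_correlation(cov_a)
    corr_p = _to_correlation(cov_p)
    return ParameterSurface(grid=grid, var_a=var_a, var_pef=var_pf,
                            var_pem=var_pm, var_e=var_e, h2=h2,
                            corr_g=corr_g, corr_p=corr_p)


def _to_correlation(cov: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = np.nan
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    return corr


def liability_to_observed(h2_liab: float, p: float) -> float:
    """Dempster-Lerner transform of liability heritability to the 0/1 scale.

    h2_obs = h2_liab * z^2 / (p (1 - p)) with z the standard normal
    density at the threshold Phi^-1(p) and p the mean incidence (here,
    mean hatch of fertile as a proportion).  Symmetric in p <-> 1-p and
    maximal at p = 0.5.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("mean incidence p must be strictly inside (0, 1)")
    if not 0.0 <= h2_liab <= 1.0:
        raise ValueError("liability heritability must be in [0, 1]")
    z = norm.pdf(norm.ppf(p))
    return h2_liab * z**2 / (p * (1.0 - p))
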