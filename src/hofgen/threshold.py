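"""Threshold (liability-scale) repeatability model for hatch of fertile.

Weekly hatched/fertile counts are modelled as binomial with a logit
link on an underlying liability:

    logit p = X b + Z_a a + Z_pf pe_hen + Z_pm pe_mate,
    hatched ~ Binomial(fertile, p)

with a ~ N(0, A sigma2_a) and identity-structured permanent environment
terms, i.e. the repeatability model moved to the liability scale while
the binomial denominator carries the per-week information content.

Estimation is penalized quasi-likelihood (PQL): iteratively reweighted
working variates z = eta + (y/n - p) / (p(1-p)) with weights n p(1-p)
are fed to the REML machinery with the working residual fixed at the
binomial value (R = diag(1/w)), and the linear predictor is refreshed
from the updated BLUE/BLUP solutions until it stabilizes.  On the logit
liability scale the implicit residual is the logistic variance
pi^2 / 3, which is what heritability computations should add to the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .components import VarianceComponents
from .design import ModelSpec, build_design
from .pedigree import Pedigree
from .reml import REMLResult, default_init, reml_fit

__all__ = ["SeparationError", "ThresholdResult", "fit_threshold_repeatability",
           "LOGISTIC_RESIDUAL_VARIANCE"]

#: variance of the standard logistic distribution (latent residual on the
#: logit liability scale)
LOGISTIC_RESIDUAL_VARIANCE = float(np.pi**2 / 3.0)


class SeparationError(ValueError):
    """The outcome is degenerate (complete separation): no liability scale fit."""


@dataclass
class ThresholdResult:
    vc: VarianceComponents       # liability-scale sigma2_a, sigma2_peF, sigma2_peM
    reml: REMLResult             # fit of the final working model
    n_outer: int
    converged: bool
    mean_incidence: float        # observed hatched/fertile, for scale transforms

    @property
    def h2_liability(self) -> float:
        s = (self.vc.scalar("aF") + self.vc.scalar("peF")
             + self.vc.scalar("peM") + LOGISTIC_RESIDUAL_VARIANCE)
        return self.vc.scalar("aF") / s


def fit_threshold_repeatability(
    table, ped: Pedigree, spec: ModelSpec | None = None,
    tol: float = 1e-5, max_iter: int = 40, inner_max_iter: int = 8,
    verbose: bool = False,
) -> ThresholdResult:
    """Fit the liability-scale repeatability model by PQL.

    Parameters
    ----------
    table:
        Weekly phenotype table; only rows with at least one fertile egg
        enter the binomial likelihood.
    tol:
        Outer convergence on the linear predictor (max absolute change)
        and on the relative change of the variance components.
    max_iter:
        Outer PQL iterations.
    inner_max_iter:
        REML iterations per outer step; the fit is warm-started, so a
        handful per step suffices.
    """
    if spec is None:
        spec = ModelSpec("threshold")
    design = build_design(table, spec, ped)
    n_f = design.binomial_n
    y = design.binomial_y
    prop = y / n_f
    if np.all(prop == 1.0) or np.all(prop == 0.0):
        raise SeparationError(
            "all records hatched (or none did): liability variance is not estimable"
        )
    pou = design.rows["pou"].to_numpy()
    pure = [np.all(prop[pou == g] == 1.0) or np.all(prop[pou == g] == 0.0)
            for g in np.unique(pou)]
    if all(pure):
        raise SeparationError(
            "every contemporary group is all-hatched or all-failed (complete separation)"
        )

    eta = logit((y + 0.5) / (n_f + 1.0))
    vc = None
    converged = False
    n_outer = 0
    for n_outer in range(1, max_iter + 1):
        p = np.clip(expit(eta), 1e-6, 1.0 - 1e-6)
        w = n_f * p * (1.0 - p)
        z = eta + (prop - p) / (p * (1.0 - p))
        design.y = z
        design.residual_weights = 1.0 / w
        if vc is None:
            vc = default_init(design)
        res = reml_fit(design, init=vc, max_iter=inner_max_iter,
                       tol=1e-8, loglik_tol=1e-10, n_em=1)
        old = np.concatenate([vc.K(t.name).ravel() for t in design.terms])
        vc = res.vc
        new = np.concatenate([vc.K(t.name).ravel() for t in design.terms])
        eta_new = design.X @ res.solve.fixed
        for t in design.terms:
            U = res.solve.random[t.name]
            eta_new = eta_new + np.einsum(
                "rm,rm->r", t.covariates, U[t.level_of_row])
        d_eta = float(np.max(np.abs(eta_new - eta)))
        d_vc = float(np.max(np.abs(new - old) / np.maximum(np.abs(old), 1e-8)))
        eta = eta_new
        if verbose:
            print(f"PQL iter {n_outer}: d_eta={d_eta:.3e} d_vc={d_vc:.3e}")
        if d_eta < tol * (1.0 + np.max(np.abs(eta))) and d_vc < 10 * tol:
            converged = True
            break
    # final polish of the variance components at the converged weights
    res = reml_fit(design, init=vc, max_iter=50, tol=1e-8, loglik_tol=1e-10, n_em=0)
    return ThresholdResult(
        vc=res.vc, reml=res, n_outer=n_outer, converged=converged,
        mean_incidence=float(np.sum(y) / np.sum(n_f)),
    )
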