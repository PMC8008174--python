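"""Henderson's mixed-model equations: assembly, solving, inverse blocks.

For the model y = Xb + sum_k Z_k u_k + e with u_k ~ N(0, A_k (x) K_k)
and R diagonal, the MME coefficient matrix is

    C = W' R^-1 W + blockdiag(0, A_1^-1 (x) K_1^-1, ...),   W = [X | Z]

whose solution gives BLUEs of b and BLUPs of u_k; the inverse of C
supplies prediction error variances and the trace terms REML needs.
The dense Cholesky path used here is comfortable up to a few thousand
equations, which covers the desk-scale analyses this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .components import VarianceComponents
from .design import DesignSystem

__all__ = ["SingularMMEError", "MMEWork", "SolveResult", "solve_mme"]


class SingularMMEError(np.linalg.LinAlgError):
    """The coefficient matrix is singular (confounded effects)."""


@dataclass
class SolveResult:
    """Fixed-effect BLUEs, per-term BLUPs and PEV diagonal blocks."""

    fixed: np.ndarray
    fixed_names: list
    random: dict         # term name -> (n_levels, m) BLUP coefficients
    pev: dict            # term name -> (n_levels, m, m) diag blocks of C^-1
    theta: np.ndarray    # stacked solution vector


class MMEWork:
    """Reusable assembly workspace for one design.

    Precomputes the stacked incidence matrix W, block offsets and the
    per-residual-class cross-product matrices M_c = W' D_c W whose
    inverse-weighted traces drive the residual updates.
    """

    def __init__(self, design: DesignSystem):
        self.design = design
        X = np.asarray(design.X, dtype=float)
        self.n, self.p = X.shape
        blocks = [sp.csr_matrix(X)] + [t.Z() for t in design.terms]
        self.W = sp.hstack(blocks, format="csr")
        self.Wt = self.W.T.tocsr()
        self.n_eq = self.W.shape[1]
        self.offsets = {}
        off = self.p
        for t in design.terms:
            self.offsets[t.name] = (off, off + t.q)
            off += t.q
        self.y = np.asarray(design.y, dtype=float)
        # W' D_c W per residual class, as COO triplets for trace extraction
        self.Mc = []
        if design.residual_kind != "fixed":
            for c in range(design.n_residual_classes):
                rows = np.flatnonzero(design.residual_class == c)
                Wc = self.W[rows]
                M = (Wc.T @ Wc).tocoo()
                self.Mc.append((M.row, M.col, M.data))
        self.class_counts = np.bincount(
            design.residual_class, minlength=design.n_residual_classes
        )

    # -- residual handling -------------------------------------------------
    def r_inv(self, vc: VarianceComponents) -> np.ndarray:
        """Per-row 1/residual-variance."""
        d = self.design
        if d.residual_kind == "fixed":
            return 1.0 / np.asarray(d.residual_weights, dtype=float)
        res = vc.residual
        if res is None or len(res) != d.n_residual_classes:
            raise ValueError("variance components do not match residual structure")
        return 1.0 / res[d.residual_class]

    def set_y(self, y: np.ndarray):
        self.y = np.asarray(y, dtype=float)

    # -- assembly ----------------------------------------------------------
    def assemble(self, vc: VarianceComponents):
        """Dense C, right-hand side, and the log-determinant of G and R."""
        rinv = self.r_inv(vc)
        Wr = self.W.multiply(rinv[:, None])
        C = (self.Wt @ Wr).toarray()
        logdet_G = 0.0
        for t in self.design.terms:
            K = vc.K(t.name)
            if K.shape[0] != t.m:
                raise ValueError(
                    f"term {t.name!r}: K order {K.shape[0] - 1} does not match design order {t.m - 1}"
                )
            sign, ld = np.linalg.slogdet(K)
            if sign <= 0:
                raise ValueError(f"term {t.name!r}: K is not positive definite")
            K_inv = np.linalg.inv(K)
            Ginv = sp.kron(t.A_inv, sp.csr_matrix(K_inv), format="coo")
            o = self.offsets[t.name][0]
            C[o + Ginv.row, o + Ginv.col] += Ginv.data
            logdet_G += t.m * t.logdet_A + t.n_levels * ld
        rhs = self.Wt @ (rinv * self.y)
        logdet_R = -float(np.sum(np.log(rinv)))
        return C, rhs, logdet_G, logdet_R

    def factor(self, C: np.ndarray):
        try:
            cho = sla.cho_factor(C, lower=True, check_finite=False)
        except np.linalg.LinAlgError as err:
            raise SingularMMEError(
                "singular mixed-model equations: "
                + self._diagnose_confounding(C)
            ) from err
        return cho

    def _diagnose_confounding(self, C: np.ndarray) -> str:
        w, v = np.linalg.eigh(0.5 * (C + C.T))
        null = v[:, np.argmin(np.abs(w))]
        idx = np.argsort(-np.abs(null))[:3]
        names = [self._equation_name(i) for i in idx]
        return f"near-null combination involves: {', '.join(names)}"

    def _equation_name(self, i: int) -> str:
        if i < self.p:
            return f"fixed '{self.design.fixed_names[i]}'"
        for t in self.design.terms:
            lo, hi = self.offsets[t.name]
            if lo <= i < hi:
                lev, coef = divmod(i - lo, t.m)
                return f"random '{t.name}' level {t.levels[lev]} coef {coef}"
        return f"equation {i}"

    def split(self, theta: np.ndarray) -> SolveResult:
        random, pev = {}, {}
        for t in self.design.terms:
            lo, hi = self.offsets[t.name]
            random[t.name] = theta[lo:hi].reshape(t.n_levels, t.m)
        return SolveResult(
            fixed=theta[: self.p], fixed_names=list(self.design.fixed_names),
            random=random, pev={}, theta=theta,
        )


def full_inverse_from_factor(cho) -> np.ndarray:
    """Dense inverse from a Cholesky factor (LAPACK dpotri)."""
    L, lower = cho
    inv, info = sla.lapack.dpotri(L, lower=lower)
    if info != 0:
        raise SingularMMEError(f"dpotri failed with info={info}")
    # dpotri fills one triangle; mirror it in place
    iu = np.triu_indices(inv.shape[0], 1)
    if lower:
        inv[iu] = inv.T[iu]
    else:
        inv.T[iu] = inv[iu]
    return inv


def solve_mme(design: DesignSystem, vc: VarianceComponents) -> SolveResult:
    """Solve the MME at fixed variance components.

    Returns BLUEs, BLUPs and, per random term, the diagonal m x m
    blocks of the inverse coefficient matrix (prediction error
    variances, used for selection accuracies).
    """
    work = MMEWork(design)
    if design.terms:
        C, rhs, _, _ = work.assemble(vc)
    else:  # pure fixed-effect (generalized least squares) degenerate case
        rinv = (np.ones(work.n) if design.residual_kind == "fixed" and design.residual_weights is None
                else work.r_inv(vc))
        Wr = work.W.multiply(rinv[:, None])
        C = (work.Wt @ Wr).toarray()
        rhs = work.Wt @ (rinv * work.y)
    cho = work.factor(C)
    theta = sla.cho_solve(cho, rhs, check_finite=False)
    Cinv = full_inverse_from_factor(cho)
    result = work.split(theta)
    for t in design.terms:
        lo, hi = work.offsets[t.name]
        block = Cinv[lo:hi, lo:hi]
        B = block.reshape(t.n_levels, t.m, t.n_levels, t.m)
        result.pev[t.name] = np.ascontiguousarray(
            B[np.arange(t.n_levels), :, np.arange(t.n_levels), :]
        )
    return result
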