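"""REML estimation of variance components for pedigree mixed models.

The maximizer combines expectation-maximization (EM) steps, which are
slow but monotone in the restricted likelihood, with average-information
(AI) quasi-Newton steps once the trajectory is stable.  AI proposals are
projected back to the positive(-semi)definite cone and step-halved until
the restricted log-likelihood does not decrease; if a proposal cannot be
rescued it falls back to an EM step, so the whole trajectory inherits
the EM stability.  All trace terms are taken from the dense inverse of
the mixed-model coefficient matrix, which is recomputed once per
iteration (desk-scale problems: a few thousand equations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .components import VarianceComponents
from .design import DesignSystem
from .mme import MMEWork, SingularMMEError, full_inverse_from_factor

__all__ = ["REMLResult", "reml_fit", "default_init"]


@dataclass
class REMLResult:
    vc: VarianceComponents
    loglik: float
    converged: bool
    n_iter: int
    boundary: list
    solve: "object"              # SolveResult at the final estimates
    history: list = field(default_factory=list)

    def report(self) -> dict:
        return {
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "boundary": list(self.boundary),
            "variance_components": self.vc.to_dict(),
        }


def default_init(design: DesignSystem) -> VarianceComponents:
    """Equal-partition starting values.

    Half of the sample variance of y goes to the residual (when it is
    estimated), the rest is split equally over the random terms, with
    diagonal K scaled so each term's average variance over the data rows
    matches its share.
    """
    vary = float(np.var(design.y))
    if vary <= 0:
        vary = 1.0
    n_terms = len(design.terms)
    has_resid = design.residual_kind != "fixed"
    share = (0.5 if has_resid else 1.0) / max(n_terms, 1)
    terms = {}
    for t in design.terms:
        mean_norm = float(np.mean(np.sum(t.covariates**2, axis=1)))
        terms[t.name] = np.eye(t.m) * (share * vary / max(mean_norm, 1e-12))
    residual = None
    if has_resid:
        # per-class empirical variances around the class means give the
        # heterogeneous-residual fits a sensible starting profile
        residual = np.empty(design.n_residual_classes)
        for c in range(design.n_residual_classes):
            yc = design.y[design.residual_class == c]
            residual[c] = 0.5 * (np.var(yc) if len(yc) > 1 else vary)
        residual = np.maximum(residual, 0.05 * vary)
    return VarianceComponents(
        terms=terms, residual=residual,
        residual_labels=design.residual_class_labels,
    )


class _State:
    """Everything the updates need from one evaluation of the MME."""

    __slots__ = ("vc", "loglik", "theta", "Cinv", "cho", "ehat", "Py",
                 "U", "T", "sse_c", "trMc", "rinv")


class _REMLDriver:
    def __init__(self, design: DesignSystem, variance_floor_scale: float = 1e-8):
        self.design = design
        self.work = MMEWork(design)
        self.vary = max(float(np.var(design.y)), 1e-12)
        self.K_floor = variance_floor_scale * self.vary
        self.resid_floor = 1e-6 * self.vary
        self.estimate_resid = design.residual_kind != "fixed"
        # parameter bookkeeping: vech(K) per term, then residual classes
        self.params = []
        for k, t in enumerate(design.terms):
            for a in range(t.m):
                for b in range(a + 1):
                    self.params.append(("K", k, a, b))
        if self.estimate_resid:
            for c in range(design.n_residual_classes):
                self.params.append(("resid", c, None, None))

    # -- parameter vector <-> VarianceComponents ---------------------------
    def to_vector(self, vc: VarianceComponents) -> np.ndarray:
        out = []
        for kind, k, a, b in self.params:
            if kind == "K":
                out.append(vc.K(self.design.terms[k].name)[a, b])
            else:
                out.append(vc.residual[k])
        return np.asarray(out)

    def from_vector(self, vec: np.ndarray) -> VarianceComponents:
        terms = {t.name: np.zeros((t.m, t.m)) for t in self.design.terms}
        residual = (np.zeros(self.design.n_residual_classes)
                    if self.estimate_resid else None)
        for val, (kind, k, a, b) in zip(vec, self.params):
            if kind == "K":
                name = self.design.terms[k].name
                terms[name][a, b] = val
                terms[name][b, a] = val
            else:
                residual[k] = val
        return self.project(VarianceComponents(
            terms=terms, residual=residual,
            residual_labels=self.design.residual_class_labels))

    def project(self, vc: VarianceComponents) -> VarianceComponents:
        """Eigenvalue-clip K matrices to the PD cone; floor residuals."""
        terms = {}
        for t in self.design.terms:
            K = vc.K(t.name)
            w, V = np.linalg.eigh(K)
            w = np.maximum(w, self.K_floor)
            terms[t.name] = (V * w) @ V.T
        residual = None
        if vc.residual is not None:
            residual = np.maximum(vc.residual, self.resid_floor)
        return VarianceComponents(terms=terms, residual=residual,
                                  residual_labels=vc.residual_labels)

    # -- one full evaluation ----------------------------------------------
    def evaluate(self, vc: VarianceComponents, need_inverse: bool = True) -> _State:
        work = self.work
        C, rhs, logdet_G, logdet_R = work.assemble(vc)
        cho = work.factor(C)
        theta = sla.cho_solve(cho, rhs, check_finite=False)
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        rinv = work.r_inv(vc)
        yPy = float(work.y @ (rinv * work.y) - theta @ rhs)
        st = _State()
        st.vc = vc
        st.loglik = -0.5 * (logdet_R + logdet_G + logdet_C + yPy)
        st.theta = theta
        st.cho = cho
        st.rinv = rinv
        st.ehat = work.y - work.W @ theta
        st.Py = rinv * st.ehat
        st.Cinv = None
        if need_inverse:
            self.complete(st)
        return st

    def complete(self, st: _State):
        """Add the inverse-based quantities (traces, BLUP blocks) to a
        state that was evaluated likelihood-only."""
        if st.Cinv is not None:
            return st
        work = self.work
        theta = st.theta
        Cinv = full_inverse_from_factor(st.cho)
        st.Cinv = Cinv
        # per-term BLUP matrices and trace matrices T_k
        st.U, st.T = {}, {}
        for t in self.design.terms:
            lo, _ = work.offsets[t.name]
            st.U[t.name] = theta[lo:lo + t.q].reshape(t.n_levels, t.m)
            Ainv = t.A_inv.tocoo()
            T = np.empty((t.m, t.m))
            for a in range(t.m):
                for b in range(t.m):
                    T[a, b] = float(np.sum(
                        Ainv.data
                        * Cinv[lo + Ainv.row * t.m + a, lo + Ainv.col * t.m + b]
                    ))
            st.T[t.name] = 0.5 * (T + T.T)
        # residual class sums of squares and traces tr(C^-1 M_c)
        if self.estimate_resid:
            st.sse_c = np.array([
                float(np.sum(st.ehat[self.design.residual_class == c] ** 2))
                for c in range(self.design.n_residual_classes)
            ])
            st.trMc = np.array([
                float(np.sum(data * Cinv[r, c_]))
                for (r, c_, data) in work.Mc
            ])
        return st

    # -- EM update ---------------------------------------------------------
    def em_update(self, st: _State) -> VarianceComponents:
        terms = {}
        for t in self.design.terms:
            U = st.U[t.name]
            quad = U.T @ (t.A_inv @ U)
            terms[t.name] = (quad + st.T[t.name]) / t.n_levels
        residual = None
        if self.estimate_resid:
            residual = (st.sse_c + st.trMc) / np.maximum(self.work.class_counts, 1)
        return self.project(VarianceComponents(
            terms=terms, residual=residual,
            residual_labels=self.design.residual_class_labels))

    # -- AI update ---------------------------------------------------------
    def scores_and_ai(self, st: _State):
        design = self.design
        work = self.work
        n_par = len(self.params)
        F = np.zeros((work.n, n_par))
        traces = np.zeros(n_par)
        Kinvs, W2s, X2s = {}, {}, {}
        for t in design.terms:
            K = st.vc.K(t.name)
            Kinv = np.linalg.inv(K)
            Kinvs[t.name] = Kinv
            W2s[t.name] = (st.U[t.name] @ Kinv)[t.level_of_row]
            X2s[t.name] = Kinv @ st.T[t.name] @ Kinv
        for i, (kind, k, a, b) in enumerate(self.params):
            if kind == "K":
                t = design.terms[k]
                cov, W2 = t.covariates, W2s[t.name]
                Kinv, X2 = Kinvs[t.name], X2s[t.name]
                if a == b:
                    F[:, i] = cov[:, a] * W2[:, a]
                    traces[i] = t.n_levels * Kinv[a, a] - X2[a, a]
                else:
                    F[:, i] = cov[:, a] * W2[:, b] + cov[:, b] * W2[:, a]
                    traces[i] = 2.0 * (t.n_levels * Kinv[a, b] - X2[a, b])
            else:
                c = k
                mask = design.residual_class == c
                F[mask, i] = st.Py[mask]
                s2 = st.vc.residual[c]
                traces[i] = (self.work.class_counts[c] / s2
                             - st.trMc[c] / s2**2)
        # P F = R^-1 F - R^-1 W C^-1 W' R^-1 F
        RF = st.rinv[:, None] * F
        PF = RF - st.rinv[:, None] * (work.W @ sla.cho_solve(
            st.cho, work.Wt @ RF, check_finite=False))
        AI = 0.5 * (F.T @ PF)
        quad = F.T @ st.Py
        score = -0.5 * (traces - quad)
        return score, AI

    # -- log-Cholesky coordinates ------------------------------------------
    # The AI (quasi-Newton) step is taken on an unconstrained
    # parametrization: K = L L' with log-transformed diagonal of L, and
    # log residual variances.  Any step then yields a PSD K, the PSD
    # boundary is pushed smoothly to -infinity, and the curvature along
    # near-boundary directions is far better behaved than in the raw
    # (co)variance coordinates.

    def _trans_params(self):
        out = []
        for k, t in enumerate(self.design.terms):
            for a in range(t.m):
                for b in range(a + 1):
                    out.append(("L", k, a, b))
        if self.estimate_resid:
            for c in range(self.design.n_residual_classes):
                out.append(("logresid", c, None, None))
        return out

    def _to_trans(self, vc: VarianceComponents):
        Ls = []
        vec = []
        for t in self.design.terms:
            K = vc.K(t.name)
            w, V = np.linalg.eigh(K)
            w = np.maximum(w, self.K_floor)
            L = np.linalg.cholesky((V * w) @ V.T)
            Ls.append(L)
            for a in range(t.m):
                for b in range(a + 1):
                    vec.append(np.log(L[a, a]) if a == b else L[a, b])
        if self.estimate_resid:
            vec.extend(np.log(np.maximum(vc.residual, self.resid_floor)))
        return np.asarray(vec), Ls

    def _from_trans(self, vec: np.ndarray) -> VarianceComponents:
        terms = {}
        i = 0
        for t in self.design.terms:
            L = np.zeros((t.m, t.m))
            for a in range(t.m):
                for b in range(a + 1):
                    L[a, b] = np.exp(min(vec[i], 50.0)) if a == b else vec[i]
                    i += 1
            terms[t.name] = L @ L.T + self.K_floor * np.eye(t.m)
        residual = None
        if self.estimate_resid:
            residual = np.exp(np.clip(vec[i:], np.log(self.resid_floor), 50.0))
        return VarianceComponents(terms=terms, residual=residual,
                                  residual_labels=self.design.residual_class_labels)

    def _jacobian(self, Ls, vc: VarianceComponents) -> np.ndarray:
        """J[natural, transformed] = d vech(K) / d (log-)Cholesky params."""
        n_nat = len(self.params)
        tp = self._trans_params()
        J = np.zeros((n_nat, len(tp)))
        nat_index = {p: i for i, p in enumerate(self.params)}
        for j, (kind, k, a, b) in enumerate(tp):
            if kind == "L":
                L = Ls[k]
                m = L.shape[0]
                E = np.zeros((m, m))
                E[a, b] = 1.0
                dK = E @ L.T + L @ E.T
                if a == b:
                    dK *= L[a, a]  # chain rule through log diagonal
                for p in range(m):
                    for q in range(p + 1):
                        J[nat_index[("K", k, p, q)], j] = dK[p, q]
            else:
                c = k
                J[nat_index[("resid", c, None, None)], j] = vc.residual[c]
        return J

    def ai_candidate(self, st: _State, max_step: float = 2.0) -> tuple | None:
        score, AI = self.scores_and_ai(st)
        vec, Ls = self._to_trans(st.vc)
        J = self._jacobian(Ls, st.vc)
        s_t = J.T @ score
        AI_t = J.T @ AI @ J
        ridge = 1e-8 * max(np.max(np.abs(np.diag(AI_t))), 1.0)
        try:
            delta = np.linalg.solve(AI_t + ridge * np.eye(len(s_t)), s_t)
        except np.linalg.LinAlgError:
            return None
        # trust region in the unconstrained coordinates
        big = np.max(np.abs(delta))
        if big > max_step:
            delta *= max_step / big
        return vec, delta

    # -- driver ------------------------------------------------------------
    def fit(self, init=None, tol=1e-6, loglik_tol=1e-8, max_iter=100,
            n_em=3, method="hybrid", verbose=False) -> REMLResult:
        vc = self.project(init) if init is not None else default_init(self.design)
        st = self.evaluate(vc)
        history = [st.loglik]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            old_vec = self.to_vector(st.vc)
            new_st = None
            if method != "em" and it > n_em:
                cand = self.ai_candidate(st)
                if cand is not None:
                    vec, delta = cand
                    for step in (1.0, 0.5, 0.25, 0.1, 0.03, 0.01):
                        try:
                            trial = self._from_trans(vec + step * delta)
                            trial_st = self.evaluate(trial, need_inverse=False)
                        except (SingularMMEError, ValueError, np.linalg.LinAlgError):
                            continue
                        if trial_st.loglik >= st.loglik - 1e-8:
                            new_st = self.complete(trial_st)
                            break
            if new_st is None:  # EM step (monotone fallback)
                new_st = self.evaluate(self.em_update(st))
            dll = new_st.loglik - st.loglik
            new_vec = self.to_vector(new_st.vc)
            rel = float(np.max(np.abs(new_vec - old_vec)
                               / np.maximum(np.abs(old_vec), 1e-4 * self.vary)))
            st = new_st
            history.append(st.loglik)
            if verbose:
                print(f"iter {it:3d} loglik {st.loglik:.8f} rel {rel:.2e}")
            if rel < tol and abs(dll) < loglik_tol:
                converged = True
                break
        # a component is reported at the boundary when it is effectively
        # zero relative to the scale of the data
        boundary = []
        edge = 1e-6 * self.vary
        for t in self.design.terms:
            if np.min(np.linalg.eigvalsh(st.vc.K(t.name))) <= edge:
                boundary.append(t.name)
        if st.vc.residual is not None and np.any(st.vc.residual <= 2.0 * self.resid_floor):
            boundary.append("residual")
        solve = self.work.split(st.theta)
        for t in self.design.terms:
            lo, _ = self.work.offsets[t.name]
            idx = lo + np.arange(t.n_levels) * t.m
            B = np.empty((t.n_levels, t.m, t.m))
            for a in range(t.m):
                for b in range(t.m):
                    B[:, a, b] = st.Cinv[idx + a, idx + b]
            solve.pev[t.name] = B
        return REMLResult(vc=st.vc, loglik=st.loglik, converged=converged,
                          n_iter=it, boundary=boundary, solve=solve,
                          history=history)


def reml_fit(design: DesignSystem, init: VarianceComponents | None = None,
             tol: float = 1e-6, loglik_tol: float = 1e-8, max_iter: int = 100,
             n_em: int = 3, method: str = "hybrid", verbose: bool = False,
             ) -> REMLResult:
    """Maximize the restricted likelihood of a design's variance components.

    Parameters
    ----------
    design:
        Output of :func:`hofgen.design.build_design`.
    init:
        Starting values; defaults to an equal partition of the sample
        variance (:func:`default_init`).
    tol, loglik_tol:
        Converged when the largest relative parameter change is below
        ``tol`` and the log-likelihood change below ``loglik_tol``.
    n_em:
        Number of initial pure-EM iterations before AI acceleration.
    method:
        ``"hybrid"`` (EM warm-up then AI with EM fallback) or ``"em"``
        (pure EM; slower, used to exercise the monotonicity property).
    """
    return _REMLDriver(design).fit(init=init, tol=tol, loglik_tol=loglik_tol,
                                   max_iter=max_iter, n_em=n_em, method=method,
                                   verbose=verbose)
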