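"""Model specifications and design systems for the HoF model ladder.

Five linear animal models plus a threshold variant are supported, all
sharing the same skeleton

    y = X b + sum_k Z_k u_k + e,     u_k ~ N(0, A_k (x) K_k)

where A_k is either the pedigree numerator relationship matrix (hen
additive genetic effects) or an identity (permanent environment of the
hen and of her mate), and K_k is a scalar variance or a coefficient
covariance matrix over Legendre regressors.

Model kinds
-----------
``cum``
    One record per hen: her mean HoF over the laying period.  Fixed:
    contemporary group (POU) and mean egg storage age.  Random: hen
    additive genetic effect only.
``rep``
    Weekly records, intra-hen correlation of one.  Fixed: POU, hen age
    (linear) and egg age covariates.  Random: hen genetic (A), hen
    permanent environment, mate permanent environment.
``frm``
    As ``rep`` but the linear age covariate is replaced by a fixed
    degree-4 Legendre lay-cycle curve.
``rrm``
    As ``frm`` plus random Legendre regressions: genetic degree 2,
    both permanent-environment terms degree 3; heterogeneous residual
    variance with one class per week of age.
``mtm``
    Early/mid/late mean HoF (weeks 27-37, 38-47, 48-58) treated as
    three traits with a full 3x3 genetic covariance and trait-specific
    residual variances (residual covariances are unidentifiable from
    disjoint per-hen averages and fixed at zero).
``threshold``
    The ``rep`` structure on the liability (logit) scale with binomial
    denominators; assembled here, fitted by :mod:`hofgen.threshold`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .legendre import AgeGrid, basis_matrix, legendre_row, standardize_age
from .pedigree import Pedigree, build_A_inverse, mendelian_variances

__all__ = ["ModelSpec", "RandomTerm", "DesignSystem", "build_design",
           "aggregate_cum", "aggregate_mtm", "MODEL_KINDS"]

MODEL_KINDS = ("cum", "rep", "frm", "rrm", "mtm", "threshold")


@dataclass(frozen=True)
class ModelSpec:
    """Which model of the ladder to fit, and its structural knobs."""

    model_kind: str
    genetic_order: int = 2       # random genetic Legendre degree (rrm)
    pe_order: int = 3            # random permanent-environment degree (rrm)
    fixed_curve_order: int = 4   # fixed lay-cycle curve degree (frm/rrm)
    age_min: int = 27
    age_max: int = 58
    residual: str | None = None  # default per kind; 'homogeneous' or 'per_week'
    mtm_bins: tuple = ((27, 37), (38, 47), (48, 58))

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")

    @property
    def residual_kind(self) -> str:
        if self.residual is not None:
            return self.residual
        if self.model_kind == "rrm":
            return "per_week"
        return "homogeneous"

    @property
    def grid(self) -> AgeGrid:
        return AgeGrid.weekly(self.age_min, self.age_max)


@dataclass
class RandomTerm:
    """One random effect: levels x regression coefficients.

    ``covariates`` holds the per-row regressor values (a single column
    of ones for scalar effects, Legendre rows for random regressions,
    trait indicators for the multitrait model).  ``structure`` selects
    the among-level covariance: the pedigree A matrix or an identity.
    """

    name: str
    levels: tuple
    level_of_row: np.ndarray
    covariates: np.ndarray
    structure: str                      # 'pedigree' | 'identity'
    A_inv: sp.csr_matrix | None = None  # inverse among-level covariance
    logdet_A: float = 0.0

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def m(self) -> int:
        return self.covariates.shape[1]

    @property
    def q(self) -> int:
        return self.n_levels * self.m

    def Z(self) -> sp.csr_matrix:
        """Incidence matrix (n_rows x n_levels*m), level-major columns."""
        n = len(self.level_of_row)
        m = self.m
        rows = np.repeat(np.arange(n), m)
        cols = (self.level_of_row[:, None] * m + np.arange(m)[None, :]).ravel()
        return sp.csr_matrix(
            (self.covariates.ravel(), (rows, cols)), shape=(n, self.q)
        )


@dataclass
class DesignSystem:
    """Assembled response, fixed design and random terms for one model."""

    y: np.ndarray
    X: np.ndarray
    fixed_names: list
    terms: list
    residual_kind: str                 # 'homogeneous' | 'classes' | 'fixed'
    residual_class: np.ndarray         # int class per row
    n_residual_classes: int
    residual_class_labels: tuple = ()
    residual_weights: np.ndarray | None = None  # fixed R diagonal (kind 'fixed')
    spec: ModelSpec | None = None
    rows: pd.DataFrame | None = None   # per-row metadata (hen_id, age_week, ...)
    binomial_n: np.ndarray | None = None   # threshold: fertile-egg denominators
    binomial_y: np.ndarray | None = None   # threshold: hatched-egg counts

    @property
    def n(self) -> int:
        return len(self.y)

    def term(self, name: str) -> RandomTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _pou_dummies(pou: pd.Series):
    """Reference-coded contemporary-group dummies (first class dropped)."""
    levels = sorted(pou.unique(), key=str)
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((pou == lev).to_numpy(dtype=float))
        names.append(f"pou[{lev}]")
    return cols, names


def _check_hens(table: pd.DataFrame, ped: Pedigree):
    missing = [h for h in table["hen_id"].unique() if h not in ped]
    if missing:
        raise ValueError(f"hens not in pedigree: {missing[:5]}{'...' if len(missing) > 5 else ''}")


def _genetic_term(table, ped, covariates) -> RandomTerm:
    level_of_row = np.array([ped.index_of(h) for h in table["hen_id"]])
    return RandomTerm(
        name="aF",
        levels=tuple(ped.animals),
        level_of_row=level_of_row,
        covariates=covariates,
        structure="pedigree",
        A_inv=build_A_inverse(ped),
        logdet_A=float(np.sum(np.log(mendelian_variances(ped)))),
    )


def _identity_term(name, ids: pd.Series, covariates) -> RandomTerm:
    levels = tuple(sorted(ids.unique(), key=str))
    index = {v: i for i, v in enumerate(levels)}
    level_of_row = np.array([index[v] for v in ids])
    return RandomTerm(
        name=name,
        levels=levels,
        level_of_row=level_of_row,
        covariates=covariates,
        structure="identity",
        A_inv=sp.identity(len(levels), format="csr"),
        logdet_A=0.0,
    )


def aggregate_cum(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse weekly records to one row per hen (mean HoF, mean egg age)."""
    t = table.dropna(subset=["hof"])
    agg = t.groupby("hen_id", sort=True).agg(
        mate_id=("mate_id", "first"),
        pou=("pou", "first"),
        hof=("hof", "mean"),
        egg_age=("egg_age", "mean"),
        n_weeks=("hof", "size"),
    ).reset_index()
    return agg


def aggregate_mtm(table: pd.DataFrame, bins=((27, 37), (38, 47), (48, 58))) -> pd.DataFrame:
    """Collapse weekly records to one row per hen per age bin (trait)."""
    t = table.dropna(subset=["hof"]).copy()
    out = []
    for k, (lo, hi) in enumerate(bins):
        part = t[(t["age_week"] >= lo) & (t["age_week"] <= hi)]
        if len(part) == 0:
            continue
        agg = part.groupby("hen_id", sort=True).agg(
            pou=("pou", "first"),
            hof=("hof", "mean"),
            egg_age=("egg_age", "mean"),
        ).reset_index()
        agg["trait"] = k
        out.append(agg)
    return pd.concat(out, ignore_index=True)


def build_design(table: pd.DataFrame, spec: ModelSpec, ped: Pedigree) -> DesignSystem:
    """Build the response, fixed design and random-term structure.

    Weekly tables are aggregated internally for ``cum`` and ``mtm``.
    Rows with undefined HoF (no fertile egg) are dropped for the linear
    models; the threshold design instead keeps the binomial counts.
    """
    _check_hens(table, ped)
    kind = spec.model_kind
    if kind == "cum":
        return _build_cum(table, spec, ped)
    if kind == "mtm":
        return _build_mtm(table, spec, ped)
    if kind == "threshold":
        return _build_threshold(table, spec, ped)
    return _build_longitudinal(table, spec, ped)


def _build_cum(table, spec, ped):
    agg = aggregate_cum(table)
    cols = [np.ones(len(agg))]
    names = ["mu"]
    pc, pn = _pou_dummies(agg["pou"])
    cols += pc; names += pn
    cols.append((agg["egg_age"] - agg["egg_age"].mean()).to_numpy())
    names.append("egg_age")
    X = np.column_stack(cols)
    aF = _genetic_term(agg, ped, np.ones((len(agg), 1)))
    return DesignSystem(
        y=agg["hof"].to_numpy(dtype=float), X=X, fixed_names=names, terms=[aF],
        residual_kind="homogeneous", residual_class=np.zeros(len(agg), dtype=int),
        n_residual_classes=1, residual_class_labels=("e",), spec=spec, rows=agg,
    )


def _fixed_longitudinal(t, spec):
    """Fixed design shared by rep/frm/rrm/threshold."""
    cols = [np.ones(len(t))]
    names = ["mu"]
    pc, pn = _pou_dummies(t["pou"])
    cols += pc; names += pn
    cols.append((t["egg_age"] - t["egg_age"].mean()).to_numpy())
    names.append("egg_age")
    tt = standardize_age(t["age_week"].to_numpy(dtype=float), spec.age_min, spec.age_max)
    if spec.model_kind in ("frm", "rrm"):
        # fixed lay-cycle curve: phi_1..phi_order on top of the mean
        Phi = legendre_row(tt, spec.fixed_curve_order)
        for j in range(1, spec.fixed_curve_order + 1):
            cols.append(Phi[:, j])
            names.append(f"curve_phi{j}")
    else:
        cols.append(t["age_week"].to_numpy(dtype=float) - t["age_week"].mean())
        names.append("age")
    return np.column_stack(cols), names, tt


def _build_longitudinal(table, spec, ped):
    t = table.dropna(subset=["hof"]).reset_index(drop=True)
    X, names, tt = _fixed_longitudinal(t, spec)
    if spec.model_kind == "rrm":
        gen_cov = legendre_row(tt, spec.genetic_order)
        pe_cov = legendre_row(tt, spec.pe_order)
    else:
        gen_cov = np.ones((len(t), 1))
        pe_cov = np.ones((len(t), 1))
    terms = [
        _genetic_term(t, ped, gen_cov),
        _identity_term("peF", t["hen_id"], pe_cov),
        _identity_term("peM", t["mate_id"], pe_cov),
    ]
    if spec.residual_kind == "per_week":
        weeks = sorted(t["age_week"].unique())
        windex = {w: i for i, w in enumerate(weeks)}
        rclass = np.array([windex[w] for w in t["age_week"]])
        nclass, labels = len(weeks), tuple(f"week{w}" for w in weeks)
    else:
        rclass, nclass, labels = np.zeros(len(t), dtype=int), 1, ("e",)
    return DesignSystem(
        y=t["hof"].to_numpy(dtype=float), X=X, fixed_names=names, terms=terms,
        residual_kind="classes" if nclass > 1 else "homogeneous",
        residual_class=rclass, n_residual_classes=nclass,
        residual_class_labels=labels, spec=spec, rows=t,
    )


def _build_mtm(table, spec, ped):
    agg = aggregate_mtm(table, spec.mtm_bins)
    n_traits = len(spec.mtm_bins)
    cols, names = [], []
    for k in range(n_traits):
        cols.append((agg["trait"] == k).to_numpy(dtype=float))
        names.append(f"mu[trait{k}]")
    pc, pn = _pou_dummies(agg["pou"])
    cols += pc; names += pn
    cols.append((agg["egg_age"] - agg["egg_age"].mean()).to_numpy())
    names.append("egg_age")
    X = np.column_stack(cols)
    trait_cov = np.zeros((len(agg), n_traits))
    trait_cov[np.arange(len(agg)), agg["trait"].to_numpy()] = 1.0
    aF = _genetic_term(agg, ped, trait_cov)
    return DesignSystem(
        y=agg["hof"].to_numpy(dtype=float), X=X, fixed_names=names, terms=[aF],
        residual_kind="classes", residual_class=agg["trait"].to_numpy(),
        n_residual_classes=n_traits,
        residual_class_labels=tuple(f"trait{k}" for k in range(n_traits)),
        spec=spec, rows=agg,
    )


def _build_threshold(table, spec, ped):
    t = table[table["eggs_fertile"] > 0].reset_index(drop=True)
    rep_spec = replace(spec, model_kind="rep") if spec.model_kind == "threshold" else spec
    X, names, tt = _fixed_longitudinal(t, rep_spec)
    terms = [
        _genetic_term(t, ped, np.ones((len(t), 1))),
        _identity_term("peF", t["hen_id"], np.ones((len(t), 1))),
        _identity_term("peM", t["mate_id"], np.ones((len(t), 1))),
    ]
    nf = t["eggs_fertile"].to_numpy(dtype=float)
    return DesignSystem(
        y=np.zeros(len(t)),  # working variate, set by the PQL loop
        X=X, fixed_names=names, terms=terms,
        residual_kind="fixed", residual_class=np.zeros(len(t), dtype=int),
        n_residual_classes=1, residual_class_labels=("binomial",),
        residual_weights=np.ones(len(t)), spec=spec, rows=t,
        binomial_n=nf, binomial_y=t["eggs_hatched"].to_numpy(dtype=float),
    )
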