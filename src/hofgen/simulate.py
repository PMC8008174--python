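"""Synthetic pedigrees and weekly hatch-of-fertile records.

The generator produces data with exactly the statistical structure the
model ladder assumes, so that every fit in the package can be checked
by parameter recovery without access to proprietary breeding-company
records.  It emulates the field data layout: hens aged 27-58 weeks,
contemporary groups (POU) of 3 successive hatch weeks shared between a
hen and her mate, egg storage age around 3.2 d, roughly 5-6 eggs set
per hen-week, and a lay-cycle mean curve rising from ~75% at onset to
~90% at peak before declining to ~65% at the end of production.

Two response modes:

``gaussian``
    Records are the linear-model liability itself (mean curve + POU +
    egg-age slope + genetic/permanent-environment regressions + normal
    residual), stored directly as ``hof``.  This is the primary
    recovery surface for the linear models; values are deliberately not
    clamped to [0, 100] because the linear models do not clamp either.
``binomial``
    The same linear predictor built on the logit scale drives
    hatched ~ Binomial(fertile, p), exercising the threshold model.

Scalar (1x1) truth variances act directly on the record scale; matrix
truths are coefficient covariances in the normalized Legendre basis.

Note that the phenotype CSV format stores egg counts and recomputes
%HoF from them, so a Gaussian-mode ``hof`` does not survive a file
round trip (it gets quantized to count ratios).  Keep Gaussian tables
in memory for recovery studies; use binomial mode for file-based
workflows — count-derived percentages are what field data deliver
anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .components import VarianceComponents
from .legendre import AgeGrid, basis_matrix, legendre_row, standardize_age
from .pedigree import Pedigree, mendelian_variances, reorder_pedigree

__all__ = [
    "SimulationConfig", "scalar_truth", "rrm_truth", "default_mean_curve",
    "simulate_pedigree", "simulate_breeding_values", "simulate_records",
    "simulate",
]

#: anchor points of the lay-cycle %HoF mean curve (age week, percent)
MEAN_CURVE_ANCHORS = (
    (27, 75.0), (31, 86.0), (37, 90.0), (42, 90.0),
    (47, 86.0), (52, 80.0), (56, 74.0), (58, 65.0),
)


def default_mean_curve(age_weeks) -> np.ndarray:
    """Population mean %HoF at each age, interpolated through the anchors."""
    xs = np.array([a for a, _ in MEAN_CURVE_ANCHORS], dtype=float)
    ys = np.array([v for _, v in MEAN_CURVE_ANCHORS], dtype=float)
    return np.interp(np.asarray(age_weeks, dtype=float), xs, ys)


def scalar_truth(total_var: float = 1.0,
                 shares: tuple = (0.05, 0.0831, 0.0105)) -> VarianceComponents:
    """Scalar truth: (genetic, hen-pe, mate-pe) shares of the total variance.

    The default shares are the repeatability-model partition used
    throughout the package's recovery studies; the residual takes the
    remainder.
    """
    s_a, s_pf, s_pm = shares
    s_e = 1.0 - s_a - s_pf - s_pm
    if s_e <= 0:
        raise ValueError("shares must sum to < 1")
    return VarianceComponents.from_scalars(
        sigma2_a=s_a * total_var, sigma2_pef=s_pf * total_var,
        sigma2_pem=s_pm * total_var, sigma2_e=s_e * total_var,
    )


def _project_cov(target: np.ndarray, grid: AgeGrid, order: int,
                 eig_floor_frac: float = 0.05) -> np.ndarray:
    """Least-squares projection of an age x age covariance onto a
    Legendre coefficient covariance.

    Smooth covariance kernels project onto nearly singular K; the
    eigenvalues are floored at a fraction of the largest so the truth is
    comfortably positive definite, as fitted coefficient covariances in
    practice are."""
    Phi = basis_matrix(grid, order)
    Pinv = np.linalg.pinv(Phi)
    K = Pinv @ target @ Pinv.T
    K = 0.5 * (K + K.T)
    w, V = np.linalg.eigh(K)
    w = np.maximum(w, eig_floor_frac * w.max())
    return (V * w) @ V.T


def _kernel_cov(var: np.ndarray, ages: np.ndarray, corr_length: float) -> np.ndarray:
    """sqrt(v v') * Gaussian correlation kernel (PSD by construction)."""
    d = ages[:, None] - ages[None, :]
    corr = np.exp(-0.5 * (d / corr_length) ** 2)
    sd = np.sqrt(var)
    return corr * np.outer(sd, sd)


def rrm_truth(grid: AgeGrid | None = None, total_var: float = 1.0,
              genetic_order: int = 2, pe_order: int = 3,
              corr_length: float = 24.0) -> VarianceComponents:
    """Random-regression truth with realistic age trajectories.

    Genetic variance ~5% of total, dipping slightly mid-lay and rising
    at the end; hen permanent environment ~8%, mate ~1%; residual
    heterogeneous over weeks (largest at onset and end of lay).  Age
    correlations decay smoothly with age distance, so adjacent weeks
    are highly correlated and distant weeks are not.
    """
    if grid is None:
        grid = AgeGrid.weekly()
    ages = np.asarray(grid.ages, dtype=float)
    u = standardize_age(ages, grid.a_min, grid.a_max)
    v_a = (0.045 + 0.020 * u**2 + 0.008 * u) * total_var
    v_pf = (0.080 + 0.025 * u**2) * total_var
    v_pm = (0.010 + 0.004 * u**2) * total_var
    K_a = _project_cov(_kernel_cov(v_a, ages, corr_length), grid, genetic_order)
    K_pf = _project_cov(_kernel_cov(v_pf, ages, corr_length), grid, pe_order)
    K_pm = _project_cov(_kernel_cov(v_pm, ages, corr_length), grid, pe_order)
    shape = 1.0 + 0.35 * u**2 - 0.10 * u
    v_e = 0.8564 * total_var * shape / np.mean(shape)
    return VarianceComponents(
        terms={"aF": K_a, "peF": K_pf, "peM": K_pm},
        residual=v_e,
        residual_labels=tuple(f"week{int(a)}" for a in ages),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic hatch-of-fertile data."""

    n_sires: int = 40
    n_dams_per_sire: int = 5
    n_offspring_per_dam: int = 4
    n_generations: int = 1
    hens_per_mate: int = 5          # mating ratio (field value unpublished)
    weeks: tuple = tuple(range(27, 59))
    pou_block_weeks: int = 3
    n_hatch_weeks: int = 12         # span of hatch dates feeding the POU blocks
    truth: VarianceComponents = field(default_factory=scalar_truth)
    pou_effect_sd: float = 0.5
    egg_age_mean: float = 3.23
    egg_age_sd: float = 1.36
    egg_age_max: float = 13.0
    egg_age_slope: float = -0.5     # response change per day of egg storage
    eggs_set_mean: float = 5.63
    eggs_set_sd: float = 1.89
    fertility: float = 0.93         # P(egg fertile), not genetically modelled
    drop_prob: float = 0.30         # independent weekly missingness
    death_hazard: float = 0.01      # weekly hazard of leaving production
    mode: str = "gaussian"
    mean_curve_scale: float = 1.0   # multiplies the %HoF mean curve
    seed: int = 0

    @property
    def grid(self) -> AgeGrid:
        return AgeGrid(tuple(self.weeks), min(self.weeks), max(self.weeks))


def simulate_pedigree(cfg: SimulationConfig, rng=None) -> tuple:
    """Hierarchical mating pedigree; returns (Pedigree, hen ids).

    Each generation mates ``n_sires`` males to ``n_dams_per_sire`` dams
    each; the phenotyped hens are the final generation's offspring
    (half- and full-sib families, so additive variance is identifiable
    from between-family resemblance).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    records = []
    sires = [f"S0_{i}" for i in range(cfg.n_sires)]
    dams = [f"D0_{i}" for i in range(cfg.n_sires * cfg.n_dams_per_sire)]
    for x in sires + dams:
        records.append((x, None, None))
    offspring = []
    for g in range(1, cfg.n_generations + 1):
        offspring = []
        k = 0
        for si, s in enumerate(sires):
            for d in dams[si * cfg.n_dams_per_sire:(si + 1) * cfg.n_dams_per_sire]:
                for _ in range(cfg.n_offspring_per_dam):
                    child = f"G{g}_{k}"
                    k += 1
                    records.append((child, s, d))
                    offspring.append(child)
        if g < cfg.n_generations:
            picks = rng.permutation(len(offspring))
            n_s, n_d = cfg.n_sires, cfg.n_sires * cfg.n_dams_per_sire
            sires = [offspring[i] for i in picks[:n_s]]
            dams = [offspring[i] for i in picks[n_s:n_s + n_d]]
    return reorder_pedigree(records), offspring


def _chol_psd(K: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix: Cholesky when PD, eigen-based otherwise
    (exact zeros stay exactly zero)."""
    K = np.atleast_2d(np.asarray(K, dtype=float))
    try:
        return np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(K)
        return V * np.sqrt(np.clip(w, 0.0, None))


def simulate_breeding_values(ped: Pedigree, K, rng) -> np.ndarray:
    """Sequential Mendelian sampling of breeding values (or coefficient
    vectors) consistent with cov = A (x) K."""
    K = np.atleast_2d(np.asarray(K, dtype=float))
    m = K.shape[0]
    L = _chol_psd(K)
    d = mendelian_variances(ped)
    a = np.zeros((ped.n, m))
    z = rng.standard_normal((ped.n, m))
    for i in range(ped.n):
        mean = np.zeros(m)
        if ped.sire[i] >= 0:
            mean += 0.5 * a[ped.sire[i]]
        if ped.dam[i] >= 0:
            mean += 0.5 * a[ped.dam[i]]
        a[i] = mean + np.sqrt(d[i]) * (L @ z[i])
    return a


def _term_effect(values: np.ndarray, ages_t: np.ndarray) -> np.ndarray:
    """Realized per-record effect: scalar value or Legendre regression."""
    if values.shape[1] == 1:
        return values[:, 0]
    Phi = legendre_row(ages_t, values.shape[1] - 1)
    return np.einsum("rm,rm->r", Phi, values)


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_records(ped: Pedigree, hens: list, cfg: SimulationConfig,
                     rng=None, breeding_values: np.ndarray | None = None,
                     ) -> pd.DataFrame:
    """Weekly records for the given hens under the configured truth."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    truth = cfg.truth
    K_a = truth.K("aF")
    K_pf = truth.K("peF") if "peF" in truth.terms else np.zeros((1, 1))
    K_pm = truth.K("peM") if "peM" in truth.terms else np.zeros((1, 1))
    if breeding_values is None:
        breeding_values = simulate_breeding_values(ped, K_a, rng)
    n_hens = len(hens)

    # mates: hens are assigned to males in randomized blocks so that a
    # male's hens are not all close relatives (random mating; keeps the
    # mate permanent environment separable from genetics)
    perm = rng.permutation(n_hens)
    mate_of_hen = np.empty(n_hens, dtype=int)
    mate_of_hen[perm] = np.arange(n_hens) // cfg.hens_per_mate
    n_mates = int(mate_of_hen.max()) + 1
    mate_ids = [f"M{j}" for j in range(n_mates)]

    def draw(K, n):
        L = _chol_psd(K)
        return rng.standard_normal((n, L.shape[0])) @ L.T

    pe_hen = draw(K_pf, n_hens)
    pe_mate = draw(K_pm, n_mates)

    # POU: each mate group hatches in one week; 3-week blocks form the group
    hatch_week = rng.integers(0, cfg.n_hatch_weeks, size=n_mates)
    pou_of_mate = hatch_week // cfg.pou_block_weeks
    pou_labels = [f"P{p}" for p in pou_of_mate]
    pou_levels = sorted(set(pou_of_mate))
    pou_effect = {p: e for p, e in zip(
        pou_levels, rng.normal(0.0, cfg.pou_effect_sd, size=len(pou_levels)))}

    weeks = np.asarray(cfg.weeks)
    n_weeks = len(weeks)
    grid = cfg.grid
    res = truth.residual
    if res is None:
        sigma_e = np.zeros(n_weeks)
    elif len(res) == 1:
        sigma_e = np.full(n_weeks, np.sqrt(res[0]))
    else:
        if len(res) != n_weeks:
            raise ValueError("truth residual length must be 1 or n_weeks")
        sigma_e = np.sqrt(np.asarray(res, dtype=float))

    hen_ped_idx = np.array([ped.index_of(h) for h in hens])
    rows = []
    for j, hen in enumerate(hens):
        # early-death hazard then independent weekly missingness
        alive = rng.random(n_weeks) >= cfg.death_hazard
        last = np.argmin(np.cumprod(alive)) if not alive.all() else n_weeks
        present = np.zeros(n_weeks, dtype=bool)
        present[:last] = rng.random(last) >= cfg.drop_prob
        idx = np.flatnonzero(present)
        if idx.size == 0:
            continue
        w = weeks[idx]
        t = standardize_age(w.astype(float), grid.a_min, grid.a_max)
        egg_age = _trunc_normal(rng, cfg.egg_age_mean, cfg.egg_age_sd,
                                0.0, cfg.egg_age_max, idx.size)
        eggs_set = np.maximum(
            1, np.rint(rng.normal(cfg.eggs_set_mean, cfg.eggs_set_sd, idx.size))
        ).astype(int)
        a_eff = _term_effect(np.repeat(breeding_values[hen_ped_idx[j]][None, :],
                                       idx.size, axis=0), t)
        pf_eff = _term_effect(np.repeat(pe_hen[j][None, :], idx.size, axis=0), t)
        pm_eff = _term_effect(np.repeat(pe_mate[mate_of_hen[j]][None, :],
                                        idx.size, axis=0), t)
        e = rng.standard_normal(idx.size) * sigma_e[idx]
        base_pct = default_mean_curve(w) * cfg.mean_curve_scale
        group = pou_of_mate[mate_of_hen[j]]
        random_part = a_eff + pf_eff + pm_eff + e
        egg_dev = egg_age - cfg.egg_age_mean
        if cfg.mode == "gaussian":
            hof = (base_pct + pou_effect[group] + cfg.egg_age_slope * egg_dev
                   + random_part)
            eggs_fertile = rng.binomial(eggs_set, cfg.fertility)
            eggs_hatched = np.rint(
                eggs_fertile * np.clip(hof, 0.0, 100.0) / 100.0).astype(int)
        elif cfg.mode == "binomial":
            # egg_age_slope is in percent HoF per day; convert locally to
            # the logit scale (d logit / d pct = 1 / (100 p (1 - p)))
            pbar = np.clip(base_pct / 100.0, 1e-6, 1 - 1e-6)
            slope_logit = cfg.egg_age_slope / (100.0 * pbar * (1.0 - pbar))
            eta = (logit(pbar) + pou_effect[group] + slope_logit * egg_dev
                   + random_part)
            eggs_fertile = rng.binomial(eggs_set, cfg.fertility)
            eggs_hatched = rng.binomial(eggs_fertile, expit(eta))
            with np.errstate(invalid="ignore", divide="ignore"):
                hof = np.where(eggs_fertile > 0,
                               100.0 * eggs_hatched / np.maximum(eggs_fertile, 1),
                               np.nan)
        else:
            raise ValueError(f"unknown mode {cfg.mode!r}")
        for k in range(idx.size):
            rows.append((hen, mate_ids[mate_of_hen[j]],
                         pou_labels[mate_of_hen[j]], int(w[k]),
                         float(egg_age[k]), int(eggs_set[k]),
                         int(eggs_fertile[k]), int(eggs_hatched[k]),
                         float(hof[k])))
    return pd.DataFrame(rows, columns=[
        "hen_id", "mate_id", "pou", "age_week", "egg_age", "eggs_set",
        "eggs_fertile", "eggs_hatched", "hof",
    ])


def simulate(cfg: SimulationConfig) -> tuple:
    """Full simulation: (Pedigree, phenotype table, truth bundle).

    Deterministic given ``cfg.seed``: identical configs produce
    bit-identical tables.
    """
    rng = np.random.default_rng(cfg.seed)
    ped, hens = simulate_pedigree(cfg, rng)
    bv = simulate_breeding_values(ped, cfg.truth.K("aF"), rng)
    table = simulate_records(ped, hens, cfg, rng, breeding_values=bv)
    truth = {
        "variance_components": cfg.truth.to_dict(),
        "mode": cfg.mode,
        "seed": cfg.seed,
        "n_hens": len(hens),
    }
    return ped, table, truth
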