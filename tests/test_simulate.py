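"""The synthetic-data generator: structure, moments, determinism."""

import numpy as np
import pandas as pd
import pytest

from hofgen.components import VarianceComponents
from hofgen.pedigree import build_A
from hofgen.phenotypes import apply_editing, validate_table
from hofgen.simulate import (SimulationConfig, rrm_truth, scalar_truth,
                             simulate, simulate_breeding_values,
                             simulate_pedigree, simulate_records)


def test_pedigree_trio_and_bookkeeping():
    cfg = SimulationConfig(n_sires=1, n_dams_per_sire=1, n_offspring_per_dam=1,
                           n_generations=1, seed=0)
    ped, hens = simulate_pedigree(cfg)
    assert ped.n == 3 and len(hens) == 1
    cfg = SimulationConfig(n_sires=3, n_dams_per_sire=2, n_offspring_per_dam=4,
                           n_generations=2, seed=1)
    ped, hens = simulate_pedigree(cfg)
    # founders + one intermediate + one final generation of offspring
    n_founders = 3 + 6
    assert len(hens) == 3 * 2 * 4
    assert ped.n == n_founders + 2 * (3 * 2 * 4)


def test_pedigree_half_sib_relationship():
    cfg = SimulationConfig(n_sires=2, n_dams_per_sire=3, n_offspring_per_dam=2,
                           seed=3)
    ped, hens = simulate_pedigree(cfg)
    A = build_A(ped)
    # two offspring of the same sire, different dams
    i = ped.index_of(hens[0])
    j = ped.index_of(hens[2])   # next dam, same sire
    assert A[i, j] == pytest.approx(0.25)
    # full sibs share both parents
    assert A[i, ped.index_of(hens[1])] == pytest.approx(0.5)


def test_breeding_values_zero_truth_and_founder_variance():
    cfg = SimulationConfig(n_sires=40, n_dams_per_sire=5, seed=5)
    ped, hens = simulate_pedigree(cfg)
    rng = np.random.default_rng(5)
    bv = simulate_breeding_values(ped, [[0.0]], rng)
    assert np.allclose(bv, 0.0)
    rng = np.random.default_rng(6)
    founders = np.flatnonzero(ped.sire < 0)
    big = simulate_breeding_values(ped, [[2.0]], rng)[founders, 0]
    n = len(founders)
    assert n >= 200
    se = 2.0 * np.sqrt(2.0 / n)   # var of sample variance of normals
    assert np.var(big) == pytest.approx(2.0, abs=3 * se)


def test_parent_offspring_covariance():
    """cov(parent, offspring) = var/2 under Mendelian sampling; averaged
    over seeds because sib clustering inflates the estimator's noise."""
    covs, var_child = [], []
    for seed in range(4):
        cfg = SimulationConfig(n_sires=120, n_dams_per_sire=5,
                               n_offspring_per_dam=2, seed=seed)
        ped, hens = simulate_pedigree(cfg)
        rng = np.random.default_rng(seed + 100)
        bv = simulate_breeding_values(ped, [[1.0]], rng)[:, 0]
        child = np.flatnonzero(ped.sire >= 0)
        covs.append(np.cov(bv[child], bv[ped.sire[child]])[0, 1])
        var_child.append(np.var(bv[child]))
    assert np.mean(covs) == pytest.approx(0.5, abs=0.07)
    assert np.mean(var_child) == pytest.approx(1.0, abs=0.08)


def test_records_constant_when_no_variance():
    truth = VarianceComponents(
        terms={"aF": [[0.0]], "peF": [[0.0]], "peM": [[0.0]]}, residual=[0.0])
    cfg = SimulationConfig(n_sires=3, n_dams_per_sire=2, n_offspring_per_dam=2,
                           truth=truth, pou_effect_sd=0.0, egg_age_slope=0.0,
                           drop_prob=0.0, death_hazard=0.0, seed=9,
                           mean_curve_scale=0.0)
    ped, hens = simulate_pedigree(cfg)
    rng = np.random.default_rng(9)
    table = simulate_records(ped, hens, cfg, rng)
    assert np.allclose(table["hof"], 0.0)
    assert len(table) == len(hens) * len(cfg.weeks)


def test_records_follow_table_structure_and_moments():
    cfg = SimulationConfig(seed=21, n_sires=25, n_dams_per_sire=5,
                           n_offspring_per_dam=3)
    ped, table, _ = simulate(cfg)
    validate_table(table, check_counts=False)
    assert table["age_week"].between(27, 58).all()
    # egg-age and eggs-set moments near the configured targets
    assert table["egg_age"].mean() == pytest.approx(3.23, abs=0.15)
    assert table["eggs_set"].mean() == pytest.approx(5.63, abs=0.3)
    # POU shared between a hen and her mate
    assert (table.groupby("mate_id")["pou"].nunique() == 1).all()
    # mean curve visible: peak ages higher than onset
    m = table.groupby("age_week")["hof"].mean()
    assert m.loc[37] > m.loc[27]
    assert m.loc[37] > m.loc[58]


def test_per_week_residual_profile_recovered_empirically():
    """With only heterogeneous residual variance, per-week empirical
    variances track the configured profile."""
    weeks = tuple(range(27, 59))
    prof = 0.5 + 1.5 * (np.linspace(-1, 1, len(weeks)) ** 2)
    truth = VarianceComponents(
        terms={"aF": [[0.0]], "peF": [[0.0]], "peM": [[0.0]]}, residual=prof)
    cfg = SimulationConfig(n_sires=100, n_dams_per_sire=5, n_offspring_per_dam=4,
                           truth=truth, pou_effect_sd=0.0, egg_age_slope=0.0,
                           drop_prob=0.0, death_hazard=0.0, seed=13,
                           mean_curve_scale=0.0)
    ped, hens = simulate_pedigree(cfg)
    rng = np.random.default_rng(13)
    table = simulate_records(ped, hens, cfg, rng)
    emp = table.groupby("age_week")["hof"].var().to_numpy()
    n = len(hens)
    se = prof * np.sqrt(2.0 / n)
    assert np.all(np.abs(emp - prof) < 4 * se)


def test_binomial_mode_counts_are_consistent():
    cfg = SimulationConfig(seed=17, n_sires=10, n_dams_per_sire=4,
                           n_offspring_per_dam=2, mode="binomial")
    ped, table, _ = simulate(cfg)
    validate_table(table)   # counts exactly consistent in binomial mode
    assert (table["eggs_hatched"] <= table["eggs_fertile"]).all()


def test_simulation_is_deterministic_given_seed():
    cfg = SimulationConfig(seed=33, n_sires=6, n_dams_per_sire=3,
                           n_offspring_per_dam=2)
    _, t1, _ = simulate(cfg)
    _, t2, _ = simulate(cfg)
    pd.testing.assert_frame_equal(t1, t2)
    _, t3, _ = simulate(SimulationConfig(seed=34, n_sires=6, n_dams_per_sire=3,
                                         n_offspring_per_dam=2))
    assert not t1.equals(t3)


def test_editing_survival_fraction_matches_missingness():
    """The fraction of hens surviving the 5-record rule matches the
    binomial expectation from the configured drop probability."""
    cfg = SimulationConfig(seed=41, n_sires=60, n_dams_per_sire=5,
                           n_offspring_per_dam=2, drop_prob=0.8,
                           death_hazard=0.0)
    ped, table, _ = simulate(cfg)
    n_hens = 60 * 5 * 2
    from scipy.stats import binom
    p_keep = 1.0 - binom.cdf(4, len(cfg.weeks), 1.0 - cfg.drop_prob)
    edited = apply_editing(table, min_records=5)
    survived = edited["hen_id"].nunique()
    se = np.sqrt(n_hens * p_keep * (1 - p_keep))
    assert abs(survived - n_hens * p_keep) < 4 * se + 2


def test_rrm_truth_is_positive_definite_with_declining_correlations():
    truth = rrm_truth(total_var=1.0)
    from hofgen.legendre import AgeGrid
    from hofgen.parameters import rrm_surface
    surf = rrm_surface(truth, AgeGrid.weekly())
    for name in ("aF", "peF", "peM"):
        assert np.linalg.eigvalsh(truth.K(name)).min() > 0
    # adjacent ages more correlated than distant ones
    assert surf.corr_g[0, 1] > surf.corr_g[0, -1]
    assert np.all(surf.h2 > 0) and np.all(surf.h2 < 1)
    # shares roughly: genetic ~5%, hen pe ~8%, mate pe ~1%
    assert scalar_truth().scalar("aF") == pytest.approx(0.05)
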