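"""REML variance-component estimation against independent oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hofgen.components import VarianceComponents
from hofgen.design import DesignSystem, ModelSpec, RandomTerm, build_design
from hofgen.reml import reml_fit
from hofgen.simulate import SimulationConfig, scalar_truth, simulate

from oracles import anova_one_way


def _one_way_design(y, groups, n_groups, X=None):
    n = len(y)
    term = RandomTerm("u", tuple(range(n_groups)), np.asarray(groups),
                      np.ones((n, 1)), "identity",
                      A_inv=sp.identity(n_groups, format="csr"))
    if X is None:
        X = np.ones((n, 1))
    return DesignSystem(y=np.asarray(y, float), X=np.asarray(X, float),
                        fixed_names=[f"b{i}" for i in range(X.shape[1])],
                        terms=[term], residual_kind="homogeneous",
                        residual_class=np.zeros(n, dtype=int),
                        n_residual_classes=1)


def test_balanced_one_way_matches_anova_closed_form():
    """For balanced one-way data with interior estimates, REML equals the
    ANOVA method-of-moments estimators."""
    rng = np.random.default_rng(10)
    n_g, n_per = 30, 8
    groups = np.repeat(np.arange(n_g), n_per)
    y = np.repeat(rng.normal(0, 1.0, n_g), n_per) + \
        rng.normal(0, 1.5, n_g * n_per)
    s2u_hat, s2e_hat = anova_one_way(y, groups)
    assert s2u_hat > 0
    res = reml_fit(_one_way_design(y, groups, n_g), tol=1e-10,
                   loglik_tol=1e-12, max_iter=200)
    assert res.converged
    assert res.vc.scalar("u") == pytest.approx(s2u_hat, abs=1e-7)
    assert res.vc.sigma2_e == pytest.approx(s2e_hat, abs=1e-7)


def test_unbalanced_random_intercept_matches_statsmodels():
    """Cross-check against statsmodels MixedLM (an independent REML
    implementation) on an unbalanced random-intercept model."""
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(7)
    rows = []
    for g in range(60):
        u = rng.normal(0, np.sqrt(0.4))
        for _ in range(int(rng.integers(3, 9))):
            x = rng.normal()
            rows.append((g, x, 1.0 + 0.5 * x + u + rng.normal(0, np.sqrt(1.3))))
    df = pd.DataFrame(rows, columns=["g", "x", "y"])
    X = np.column_stack([np.ones(len(df)), df["x"]])
    res = reml_fit(_one_way_design(df["y"], df["g"], 60, X=X),
                   tol=1e-10, loglik_tol=1e-12, max_iter=200)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = smf.mixedlm("y ~ x", df, groups=df["g"]).fit(reml=True)
    assert res.vc.scalar("u") == pytest.approx(float(m.cov_re.iloc[0, 0]), rel=1e-4)
    assert res.vc.sigma2_e == pytest.approx(float(m.scale), rel=1e-4)
    assert res.solve.fixed == pytest.approx(
        [m.params["Intercept"], m.params["x"]], rel=1e-5)


def test_em_loglik_is_monotone():
    rng = np.random.default_rng(3)
    n_g, n_per = 20, 4
    groups = np.repeat(np.arange(n_g), n_per)
    y = np.repeat(rng.normal(0, 0.8, n_g), n_per) + rng.normal(0, 1.1, n_g * n_per)
    res = reml_fit(_one_way_design(y, groups, n_g), method="em", max_iter=60)
    diffs = np.diff(res.history)
    assert np.all(diffs > -1e-9)


def test_zero_genetic_variance_hits_boundary():
    """Half-sib families simulated with zero additive variance: the
    genetic component is identifiable through A and is driven to the
    boundary."""
    truth = VarianceComponents(
        terms={"aF": [[0.0]], "peF": [[0.1]], "peM": [[0.05]]},
        residual=[1.0])
    cfg = SimulationConfig(seed=19, n_sires=12, n_dams_per_sire=4,
                           n_offspring_per_dam=3, truth=truth,
                           pou_effect_sd=0.3, mean_curve_scale=0.0)
    ped, table, _ = simulate(cfg)
    design = build_design(table, ModelSpec("rep"), ped)
    res = reml_fit(design, max_iter=60)
    total = (res.vc.scalar("aF") + res.vc.scalar("peF")
             + res.vc.scalar("peM") + res.vc.sigma2_e)
    assert res.vc.scalar("aF") / total < 0.02
    assert "aF" in res.boundary


def test_rep_recovery_single_seed_smoke():
    """One 300-hen repeatability simulation: estimates land near the
    generating shares (tight recovery is exercised at scale elsewhere)."""
    cfg = SimulationConfig(seed=23, n_sires=15, n_dams_per_sire=5,
                           n_offspring_per_dam=4, truth=scalar_truth(1.0),
                           pou_effect_sd=0.5, mean_curve_scale=0.0)
    ped, table, _ = simulate(cfg)
    res = reml_fit(build_design(table, ModelSpec("rep"), ped), max_iter=60)
    assert res.converged
    total = (res.vc.scalar("aF") + res.vc.scalar("peF")
             + res.vc.scalar("peM") + res.vc.sigma2_e)
    assert total == pytest.approx(1.0, abs=0.15)
    assert res.vc.scalar("aF") / total == pytest.approx(0.05, abs=0.05)
    assert res.vc.scalar("peF") / total == pytest.approx(0.0831, abs=0.06)


def test_rrm_order_zero_nests_repeatability():
    """A random regression with all orders 0 and homogeneous residual is
    the repeatability model in a rescaled basis: variance components
    agree to high precision on the same data."""
    cfg = SimulationConfig(seed=29, n_sires=8, n_dams_per_sire=4,
                           n_offspring_per_dam=3, truth=scalar_truth(1.0),
                           pou_effect_sd=0.4, mean_curve_scale=0.0)
    ped, table, _ = simulate(cfg)
    rep = reml_fit(build_design(table, ModelSpec("frm"), ped),
                   tol=1e-9, loglik_tol=1e-11, max_iter=300)
    spec0 = ModelSpec("rrm", genetic_order=0, pe_order=0,
                      residual="homogeneous")
    rrm = reml_fit(build_design(table, spec0, ped),
                   tol=1e-9, loglik_tol=1e-11, max_iter=300)
    # order-0 normalized Legendre basis is the constant 1/sqrt(2):
    # record-scale variance = K / 2
    for name in ("aF", "peF", "peM"):
        assert rrm.vc.K(name)[0, 0] / 2.0 == pytest.approx(
            rep.vc.scalar(name), abs=1e-6)
    assert rrm.vc.sigma2_e == pytest.approx(rep.vc.sigma2_e, abs=1e-6)
    assert rrm.loglik == pytest.approx(rep.loglik, abs=1e-6)
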