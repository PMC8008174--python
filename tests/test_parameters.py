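"""Heritability, repeatability, parameter surfaces, scale transforms."""

import numpy as np
import pytest
from scipy.stats import norm

from hofgen.components import VarianceComponents
from hofgen.legendre import AgeGrid, basis_matrix, legendre_row, standardize_age
from hofgen.parameters import (heritability_scalar, liability_to_observed,
                               rrm_surface)


def test_heritability_scalar_pure_genetic():
    vc = VarianceComponents.from_scalars(1.0, 0.0, 0.0, 0.0)
    h2, re = heritability_scalar(vc)
    assert h2 == 1.0 and re == 1.0


def test_heritability_scalar_repeatability_partition():
    """The repeatability-model partition: genetic 5%, hen permanent
    environment 8.31%, mate permanent environment 1.05% of a unit
    phenotypic variance."""
    vc = VarianceComponents.from_scalars(0.05, 0.0831, 0.0105, 0.8564)
    h2, re = heritability_scalar(vc)
    assert h2 == pytest.approx(0.05, abs=1e-12)
    assert vc.scalar("peF") / 1.0 == pytest.approx(0.0831)
    assert vc.scalar("peM") / 1.0 == pytest.approx(0.0105)
    assert re == pytest.approx(0.1436, abs=1e-10)


def test_heritability_shares_sum_to_one():
    rng = np.random.default_rng(3)
    for _ in range(10):
        s = rng.uniform(0.01, 1.0, size=4)
        vc = VarianceComponents.from_scalars(*s)
        h2, re = heritability_scalar(vc)
        total = s.sum()
        assert h2 + (s[1] + s[2]) / total + s[3] / total == pytest.approx(1.0)
        assert re == pytest.approx((s[0] + s[1] + s[2]) / total)


def test_heritability_zero_variance_errors():
    vc = VarianceComponents.from_scalars(0.0, 0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        heritability_scalar(vc)


def _vc_rrm(K_a, K_pf, K_pm, resid):
    return VarianceComponents(terms={"aF": K_a, "peF": K_pf, "peM": K_pm},
                              residual=resid)


def test_surface_constant_ratio_when_proportional():
    """K_a proportional to K_pf with no mate or residual variance gives a
    flat heritability c/(c+1)."""
    grid = AgeGrid.weekly()
    rng = np.random.default_rng(8)
    B = rng.normal(size=(4, 4))
    K = B @ B.T
    c = 0.3
    surf = rrm_surface(_vc_rrm(c * K[:3, :3], K, np.zeros((4, 4)),
                               np.zeros(grid.n)),
                       grid, genetic_order=2, pe_order=3)
    # proportionality requires equal orders; rebuild with matching orders
    surf = rrm_surface(_vc_rrm(c * K, K, np.zeros((4, 4)), np.zeros(grid.n)),
                       grid, genetic_order=3, pe_order=3)
    assert np.allclose(surf.h2, c / (c + 1.0))
    assert np.allclose(np.diag(surf.corr_g), 1.0)


def test_surface_matches_elementwise_oracle():
    grid = AgeGrid((27, 40, 58), 27, 58)
    rng = np.random.default_rng(21)
    mats = []
    for m in (3, 4, 4):
        B = rng.normal(size=(m, m))
        mats.append(B @ B.T)
    K_a, K_pf, K_pm = mats
    resid = rng.uniform(0.5, 1.5, size=3)
    surf = rrm_surface(_vc_rrm(K_a, K_pf, K_pm, resid), grid)
    for i, ai in enumerate(grid.ages):
        ti = standardize_age(ai, 27, 58)
        phi_g = legendre_row(ti, 2)
        phi_p = legendre_row(ti, 3)
        va = phi_g @ K_a @ phi_g
        vp = va + phi_p @ K_pf @ phi_p + phi_p @ K_pm @ phi_p + resid[i]
        assert surf.var_a[i] == pytest.approx(va, rel=1e-12)
        assert surf.h2[i] == pytest.approx(va / vp, rel=1e-12)
        for j, aj in enumerate(grid.ages):
            tj = standardize_age(aj, 27, 58)
            phj = legendre_row(tj, 2)
            cov = phi_g @ K_a @ phj
            expect = cov / np.sqrt(va * (phj @ K_a @ phj))
            assert surf.corr_g[i, j] == pytest.approx(expect, rel=1e-10)


def test_surface_consistent_with_scalar_model():
    """Diagonal-constant K in the order-0 basis with equal per-week
    residual reproduces the scalar heritability."""
    grid = AgeGrid.weekly()
    # order-0 normalized basis: record variance = K / 2
    vc = _vc_rrm([[2 * 0.05]], [[2 * 0.0831]], [[2 * 0.0105]],
                 np.full(grid.n, 0.8564))
    surf = rrm_surface(vc, grid, genetic_order=0, pe_order=0)
    h2_scalar, _ = heritability_scalar(
        VarianceComponents.from_scalars(0.05, 0.0831, 0.0105, 0.8564))
    assert np.allclose(surf.h2, h2_scalar)
    assert surf.h2_average == pytest.approx(h2_scalar)


def test_surface_phenotypic_correlation_includes_residual_on_diagonal_only():
    grid = AgeGrid((27, 58), 27, 58)
    K = np.eye(1) * 2.0
    surf = rrm_surface(_vc_rrm(K, np.zeros((1, 1)), np.zeros((1, 1)),
                               np.array([1.0, 1.0])),
                       grid, genetic_order=0, pe_order=0)
    # genetic corr 1 across ages, phenotypic diluted by residual
    assert surf.corr_g[0, 1] == pytest.approx(1.0)
    assert surf.corr_p[0, 1] == pytest.approx(1.0 / 2.0)


def test_liability_transform_reference_value():
    """Liability heritability 0.11 at mean incidence 0.844 maps to 0.05
    on the observed scale (two decimals)."""
    h2_obs = liability_to_observed(0.11, 0.844)
    assert round(h2_obs, 2) == 0.05
    assert h2_obs == pytest.approx(0.0478, abs=5e-4)


def test_liability_transform_edge_cases():
    assert liability_to_observed(0.0, 0.3) == 0.0
    z0 = norm.pdf(0.0)
    assert liability_to_observed(0.4, 0.5) == pytest.approx(0.4 * z0**2 / 0.25)
    assert liability_to_observed(0.4, 0.5) == pytest.approx(0.4 * 2 / np.pi)
    with pytest.raises(ValueError):
        liability_to_observed(0.1, 0.0)
    with pytest.raises(ValueError):
        liability_to_observed(0.1, 1.0)
    with pytest.raises(ValueError):
        liability_to_observed(1.2, 0.5)


def test_liability_transform_symmetric_and_maximal_at_half():
    ps = np.linspace(0.05, 0.95, 19)
    vals = np.array([liability_to_observed(0.3, p) for p in ps])
    assert np.allclose(vals, vals[::-1], atol=1e-12)
    assert np.argmax(vals) == len(ps) // 2


def test_corr_g_is_psd_when_K_is():
    rng = np.random.default_rng(12)
    for _ in range(5):
        B = rng.normal(size=(3, 3))
        K = B @ B.T + 0.1 * np.eye(3)
        surf = rrm_surface(_vc_rrm(K, np.eye(4), np.eye(4),
                                   np.ones(AgeGrid.weekly().n)),
                           AgeGrid.weekly())
        assert np.linalg.eigvalsh(surf.corr_g).min() >= -1e-8
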