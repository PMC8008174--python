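"""Selection intensity, single-trait responses and the selection index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from hofgen.selection import (IndexInputs, SelectionInputs, index_weights,
                              model_comparison_report, response_index,
                              response_repeated, response_single,
                              selection_intensity)


def test_intensity_at_half_is_two_phi_zero():
    assert selection_intensity(0.5) == pytest.approx(2 * norm.pdf(0.0), abs=1e-10)
    assert selection_intensity(0.5) == pytest.approx(0.7979, abs=1e-4)


def test_intensity_vanishes_as_everyone_is_selected():
    assert selection_intensity(0.999999) < 1e-4
    with pytest.raises(ValueError):
        selection_intensity(0.0)
    with pytest.raises(ValueError):
        selection_intensity(1.0)


def test_intensity_matches_truncated_normal_monte_carlo():
    """i(p) equals the mean of the selected top fraction of a standard
    normal; checked by simulation at p = 0.2 and 0.5."""
    rng = np.random.default_rng(123)
    z = rng.standard_normal(1_000_000)
    for p in (0.2, 0.5):
        k = int(p * len(z))
        top = np.sort(z)[-k:]
        se = top.std() / np.sqrt(k)
        assert selection_intensity(p) == pytest.approx(top.mean(), abs=3 * se)
    assert selection_intensity(0.2) == pytest.approx(1.400, abs=2e-3)


def test_response_single_reference_cases():
    assert response_single(SelectionInputs(i=1, r=1, sigma_a=1, L=1)) == 1.0
    assert response_single(SelectionInputs(i=0.8, r=0.0, sigma_a=2, L=1)) == 0.0
    si = SelectionInputs(i=0.798, r=0.47, sigma_a=3.1, L=2.5)
    assert response_single(si) == pytest.approx(0.798 * 0.47 * 3.1 / 2.5)


def test_response_repeated_multiplier():
    base = SelectionInputs(i=0.9, r=0.5, sigma_a=2.0, L=1.5, n=1, re=0.3)
    assert response_repeated(base) == pytest.approx(response_single(base))
    same = SelectionInputs(i=0.9, r=0.5, sigma_a=2.0, L=1.5, n=7, re=1.0)
    assert response_repeated(same) == pytest.approx(response_single(same))
    si = SelectionInputs(i=1.0, r=1.0, sigma_a=1.0, L=1.0, n=10, re=0.145)
    assert response_repeated(si) == pytest.approx(np.sqrt(10 / 2.305), abs=1e-3)
    assert response_repeated(si) == pytest.approx(2.083, abs=1e-3)
    assert response_repeated(si, sqrt_multiplier=False) == pytest.approx(10 / 2.305, rel=1e-6)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.floats(0.01, 0.99), st.integers(2, 40))
def test_response_repeated_monotone_in_n_and_re(re, n):
    si_lo = SelectionInputs(i=1, r=0.5, sigma_a=1, L=1, n=n, re=re)
    si_hi = SelectionInputs(i=1, r=0.5, sigma_a=1, L=1, n=n + 1, re=re)
    assert response_repeated(si_hi) >= response_repeated(si_lo)
    si_re = SelectionInputs(i=1, r=0.5, sigma_a=1, L=1, n=n, re=min(re + 0.01, 1.0))
    assert response_repeated(si_re) <= response_repeated(si_lo)


def test_index_weights_reference_cases():
    one = IndexInputs(P=[[2.0]], G=[[2.0]], a=[1.0])
    assert index_weights(one) == pytest.approx([1.0])
    zero = IndexInputs(P=np.eye(3), G=np.zeros((3, 3)), a=np.ones(3))
    assert np.allclose(index_weights(zero), 0.0)


def test_index_weights_match_explicit_inverse():
    rng = np.random.default_rng(17)
    B = rng.normal(size=(3, 3))
    P = B @ B.T + 3 * np.eye(3)
    C = rng.normal(size=(3, 3))
    G = 0.3 * (C @ C.T)
    a = np.ones(3)
    ix = IndexInputs(P=P, G=G, a=a)
    assert np.allclose(index_weights(ix), np.linalg.inv(P) @ G @ a, atol=1e-12)


def test_index_response_degenerates_to_single_trait():
    """With one trait, P = G and unit weight, the index response equals
    the single-trait response at full accuracy."""
    sigma2 = 4.0
    ix = IndexInputs(P=[[sigma2]], G=[[sigma2]], a=[1.0])
    R, var_I = response_index(ix, i=0.7979, L=2.0)
    assert var_I == pytest.approx(sigma2)
    si = SelectionInputs(i=0.7979, r=1.0, sigma_a=np.sqrt(sigma2), L=2.0)
    assert R == pytest.approx(response_single(si))
    zero_weight = IndexInputs(P=[[sigma2]], G=[[sigma2]], a=[0.0])
    assert response_index(zero_weight, i=1.0)[0] == 0.0


def test_index_three_traits_from_multitrait_parameters():
    """Three-trait index built from heritabilities (0.14, 0.15, 0.07) and
    genetic correlations (0.86, 0.70, 0.94) on unit phenotypic variances,
    equal weights; checked against dense algebra."""
    h2 = np.array([0.14, 0.15, 0.07])
    rg = {(0, 1): 0.86, (0, 2): 0.70, (1, 2): 0.94}
    sa = np.sqrt(h2)
    G = np.diag(h2).astype(float)
    for (i, j), r in rg.items():
        G[i, j] = G[j, i] = r * sa[i] * sa[j]
    P = np.eye(3)
    a = np.ones(3)
    ix = IndexInputs(P=P, G=G, a=a)
    b = index_weights(ix)
    R, var_I = response_index(ix, i=1.0, L=1.0)
    # oracle: explicit inverse and quadratic form
    b_oracle = np.linalg.inv(P) @ G @ a
    assert np.allclose(b, b_oracle)
    assert var_I == pytest.approx(float(b_oracle @ P @ b_oracle), rel=1e-12)
    assert R == pytest.approx(np.sqrt(var_I), rel=1e-12)
    assert var_I > 0


def test_index_variance_nonnegative_on_random_systems():
    rng = np.random.default_rng(31)
    for _ in range(20):
        B = rng.normal(size=(4, 4))
        P = B @ B.T + 4 * np.eye(4)
        C = rng.normal(size=(4, 4))
        G = 0.2 * (C @ C.T)
        a = rng.normal(size=4)
        _, var_I = response_index(IndexInputs(P=P, G=G, a=a), i=1.0)
        assert var_I >= 0
        # consistency bound: Var(I) = a'G P^-1 G a computed densely
        bound = float(a @ G @ np.linalg.inv(P) @ G @ a)
        assert var_I == pytest.approx(bound, rel=1e-10)


def test_model_comparison_report_shape():
    rep = model_comparison_report({"rep": 0.0, "rrm": 0.07}, 84.4)
    assert list(rep.columns) == ["model", "gain_per_year", "pct_of_mean"]
    assert len(rep) == 2
    row = rep.set_index("model").loc["rrm"]
    assert row["pct_of_mean"] == pytest.approx(100 * 0.07 / 84.4)
    zero = rep.set_index("model").loc["rep"]
    assert zero["gain_per_year"] == 0.0 and zero["pct_of_mean"] == 0.0


def test_selection_input_validation():
    with pytest.raises(ValueError):
        SelectionInputs(i=1, r=1.2, sigma_a=1)
    with pytest.raises(ValueError):
        SelectionInputs(i=1, r=0.5, sigma_a=1, n=0.5)
    with pytest.raises(ValueError):
        SelectionInputs(i=1, r=0.5, sigma_a=1, L=0.0)
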