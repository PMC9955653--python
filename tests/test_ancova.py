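"""ANCOVA fitting, contrast estimation, and the bias-correction factor."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stdcontrast import (
    ANCOVAData,
    ContrastSpec,
    contrast_estimate,
    fit_ancova,
    unbias_factor,
    variance_factor,
)
from conftest import make_design
from stdcontrast.simulate import generate_dataset

# frozen from R: gamma(5) / (sqrt(5) * gamma(4.5))
U_NU10_R = 0.9227456081


def _full_design_lstsq(data):
    """Independent oracle: one-hot group indicators + covariates, np.linalg.lstsq."""
    g = data.n_groups
    ind = np.eye(g)[data.group_index]
    X = np.hstack([ind, data.x])
    coef, _, _, _ = np.linalg.lstsq(X, data.y, rcond=None)
    resid = data.y - X @ coef
    return coef[:g], coef[g:], float(resid @ resid)


@pytest.mark.parametrize("seed", [42, 7, 101])
def test_fit_matches_full_design_matrix_oracle(seed):
    data = generate_dataset(make_design(p=2, theta=0.25), 18, seed=seed)
    fit = fit_ancova(data)
    mu, beta, sse = _full_design_lstsq(data)
    np.testing.assert_allclose(fit.mu, mu, atol=1e-8)
    np.testing.assert_allclose(fit.beta, beta, atol=1e-8)
    assert abs(fit.sse - sse) < 1e-8


def test_zero_slope_gives_group_mean_adjusted_means():
    rng = np.random.default_rng(0)
    group = np.repeat([0, 1], 12)
    x = rng.standard_normal((24, 1))
    y = np.where(group == 0, 1.0, 3.0) + rng.standard_normal(24)  # beta = 0
    fit = fit_ancova(ANCOVAData(group=group, y=y, x=x))
    ybar = [y[group == 0].mean(), y[group == 1].mean()]
    # beta-hat is near zero, so adjusted means sit near the raw group means
    assert abs(fit.beta[0]) < 0.5
    np.testing.assert_allclose(fit.mu_adjusted, ybar, atol=0.1)
    # and the identity mu*_i - mu_i = xbar_grand' beta holds exactly
    np.testing.assert_allclose(
        fit.mu_adjusted - fit.mu, np.full(2, fit.xbar_grand @ fit.beta), atol=1e-12
    )


def test_location_shift_moves_means_only(small_dataset):
    fit0 = fit_ancova(small_dataset)
    shifted = ANCOVAData(
        group=small_dataset.group, y=small_dataset.y + 7.5, x=small_dataset.x
    )
    fit1 = fit_ancova(shifted)
    np.testing.assert_allclose(fit1.mu, fit0.mu + 7.5, atol=1e-8)
    np.testing.assert_allclose(fit1.mu_adjusted, fit0.mu_adjusted + 7.5, atol=1e-8)
    np.testing.assert_allclose(fit1.beta, fit0.beta, atol=1e-10)
    assert abs(fit1.sse - fit0.sse) < 1e-8


@settings(deadline=None, max_examples=20, derandomize=True)
@given(scale=st.floats(min_value=0.05, max_value=20.0))
def test_scale_equivariance(scale):
    """psi-hat scales with the response; psi-star and T_O are scale-free."""
    data = generate_dataset(make_design(p=1, theta=0.25), 18, seed=3)
    c = ContrastSpec(np.array([1.0, -0.5, -0.5]))
    est0 = contrast_estimate(fit_ancova(data), c)
    est1 = contrast_estimate(
        fit_ancova(ANCOVAData(group=data.group, y=scale * data.y, x=data.x)), c
    )
    assert est1.psi_hat == pytest.approx(scale * est0.psi_hat, abs=1e-10 * scale)
    assert est1.psi_star_hat == pytest.approx(est0.psi_star_hat, abs=1e-10)
    assert est1.t_obs == pytest.approx(est0.t_obs, abs=1e-10)


def test_within_group_permutation_invariance(small_dataset):
    rng = np.random.default_rng(9)
    perm = np.arange(small_dataset.n_total)
    for gi in range(small_dataset.n_groups):
        idx = np.flatnonzero(small_dataset.group_index == gi)
        perm[idx] = rng.permutation(idx)
    permuted = ANCOVAData(
        group=small_dataset.group[perm], y=small_dataset.y[perm], x=small_dataset.x[perm]
    )
    f0, f1 = fit_ancova(small_dataset), fit_ancova(permuted)
    np.testing.assert_allclose(f0.mu, f1.mu, atol=1e-10)
    np.testing.assert_allclose(f0.beta, f1.beta, atol=1e-10)
    assert f0.sse == pytest.approx(f1.sse, abs=1e-8)


def test_contrast_estimate_identities(small_dataset):
    fit = fit_ancova(small_dataset)
    c = ContrastSpec(np.array([1.0, -0.5, -0.5]))
    est = contrast_estimate(fit, c)
    # contrast of intercepts equals contrast of adjusted means
    assert est.psi_hat == pytest.approx(
        float(c.coefficients @ fit.mu_adjusted), abs=1e-10
    )
    assert est.Q >= 0 and est.V >= est.a
    assert est.t_obs * np.sqrt(est.V) == pytest.approx(est.psi_star_hat, abs=1e-10)
    assert 0 < est.u < 1


def test_zero_disparity_when_group_covariate_means_equal():
    # identical covariate values in every group -> Q = 0 and V = a
    rng = np.random.default_rng(1)
    x_block = rng.standard_normal((8, 1))
    group = np.repeat([0, 1, 2], 8)
    x = np.vstack([x_block] * 3)
    y = rng.standard_normal(24) + 0.5 * x[:, 0]
    est = contrast_estimate(
        fit_ancova(ANCOVAData(group=group, y=y, x=x)),
        ContrastSpec(np.array([1.0, -0.5, -0.5])),
    )
    assert est.Q == pytest.approx(0.0, abs=1e-10)
    assert est.V == pytest.approx(est.a, abs=1e-10)


def test_disparity_quadratic_form_matches_bruteforce(small_dataset):
    fit = fit_ancova(small_dataset)
    c = np.array([1.0, -0.5, -0.5])
    est = contrast_estimate(fit, ContrastSpec(c))
    h = c @ fit.xbar_groups
    q_brute = h @ np.linalg.inv(fit.v_xx) @ h
    assert est.Q == pytest.approx(q_brute, abs=1e-8)


def test_variance_factor_learning_disabilities(example):
    v = variance_factor(example["sizes"], example["contrast"], example["Q"])
    assert round(v, 4) == 0.0814


class TestUnbiasFactor:
    def test_reference_value(self):
        assert unbias_factor(10) == pytest.approx(U_NU10_R, abs=1e-9)

    def test_large_nu_limit(self):
        assert unbias_factor(1e6) == pytest.approx(1.0, abs=1e-5)

    def test_small_nu_closed_forms(self):
        # Gamma(1)/ (sqrt(1) Gamma(1/2)) = 1/sqrt(pi);  Gamma(3/2)/(sqrt(3/2) Gamma(1))
        assert unbias_factor(2) == pytest.approx(1.0 / np.sqrt(np.pi), abs=1e-12)
        assert unbias_factor(3) == pytest.approx(
            0.5 * np.sqrt(np.pi) / np.sqrt(1.5), abs=1e-12
        )

    def test_agrees_with_hedges_approximation(self):
        # direct evaluation shows the 1 - 3/(4 nu - 1) shortcut is within
        # 0.002 from nu = 5 on (0.0072 at nu = 2, 0.0021 at nu = 4)
        for nu in range(5, 201):
            assert abs(unbias_factor(nu) - (1.0 - 3.0 / (4.0 * nu - 1.0))) < 0.002

    def test_bounds_and_domain(self):
        for nu in (2, 5, 30):
            assert 0.0 < unbias_factor(nu) < 1.0
        with pytest.raises(ValueError, match="nu > 1"):
            unbias_factor(1)


def test_bias_correction_reduces_bias():
    """Over many replicates at nu = 11 the corrected estimator is less biased."""
    rng = np.random.default_rng(2024)
    nu, psi_star, V, sigma_sq = 11, 1.0, 0.3178, 3.2728
    reps = 20_000
    psi_hat = rng.normal(psi_star * np.sqrt(sigma_sq), np.sqrt(sigma_sq * V), reps)
    sig_hat = np.sqrt(sigma_sq * rng.chisquare(nu, reps) / nu)
    psi_star_hat = psi_hat / sig_hat
    u = unbias_factor(nu)
    raw_bias = abs(psi_star_hat.mean() - psi_star)
    corrected_bias = abs(u * psi_star_hat.mean() - psi_star)
    assert corrected_bias < raw_bias
    assert raw_bias > 0.01  # the raw estimator is visibly biased upward at nu = 11


class TestValidation:
    def test_collinear_covariates_fail_loudly(self):
        rng = np.random.default_rng(5)
        x1 = rng.standard_normal(18)
        x = np.column_stack([x1, 2.0 * x1])  # exactly collinear
        data = ANCOVAData(group=np.repeat([0, 1, 2], 6), y=rng.standard_normal(18), x=x)
        with pytest.raises(ValueError, match="collinear"):
            fit_ancova(data)

    def test_insufficient_degrees_of_freedom(self):
        rng = np.random.default_rng(6)
        data = ANCOVAData(
            group=np.array([0, 0, 1, 1]), y=rng.standard_normal(4),
            x=rng.standard_normal((4, 2)),
        )
        with pytest.raises(ValueError, match="degrees of freedom"):
            fit_ancova(data)

    def test_contrast_must_sum_to_zero(self):
        with pytest.raises(ValueError, match="sum to zero"):
            ContrastSpec(np.array([1.0, -0.5, -0.4]))
        with pytest.raises(ValueError, match="nonzero"):
            ContrastSpec(np.array([0.0, 0.0, 0.0]))

    def test_contrast_length_checked_against_groups(self, small_dataset):
        fit = fit_ancova(small_dataset)
        with pytest.raises(ValueError, match="does not match"):
            contrast_estimate(fit, ContrastSpec(np.array([1.0, -1.0])))
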