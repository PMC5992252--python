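import numpy as np
import pytest

from humpdec import (DEFAULT_TOY, default_penalties, fit_sse, select_lambdas,
                     toy_components)
from humpdec.basis import difference_matrix


def two_component_truth(ages, hump_height=1e-3):
    """Gompertz senescence + log-Gaussian hump on the standard grid."""
    gamma_S = 4e-5 * np.exp(0.095 * (ages - 10))
    gamma_H = hump_height * np.exp(-((ages - 22.0) ** 2) / (2 * 5.0**2))
    return gamma_H, gamma_S


def test_noiseless_component_recovery(ages):
    gH, gS = two_component_truth(ages)
    mu = gH + gS
    e = np.full(ages.size, 1e7)
    fit = fit_sse(e * mu, e, ages=ages)
    assert fit.converged
    core_H = gH > 0.1 * mu
    core_S = gS > 0.1 * mu
    assert np.max(np.abs(fit.gamma_H[core_H] / gH[core_H] - 1)) < 0.05
    assert np.max(np.abs(fit.gamma_S[core_S] / gS[core_S] - 1)) < 0.05


def test_sum_matches_total(ages):
    gH, gS = two_component_truth(ages)
    e = np.full(ages.size, 1e7)
    fit = fit_sse(e * (gH + gS), e, ages=ages)
    assert np.max(np.abs(fit.mu_hat / (gH + gS) - 1)) < 0.01


def test_shape_constraints_hold(ages):
    gH, gS = two_component_truth(ages)
    e = np.full(ages.size, 1e5)
    d = np.random.default_rng(2).poisson(e * (gH + gS)).astype(float)
    fit = fit_sse(d, e, ages=ages)
    assert fit.converged
    assert fit.max_shape_violation < 1e-8
    # the constraints transfer from coefficients to the curves
    assert np.min(np.diff(fit.gamma_S)) > -1e-12 * fit.gamma_S.max()
    d2 = difference_matrix(ages.size, 2) @ np.log(fit.gamma_H)
    assert d2.max() < 1e-6


def test_gompertz_only_attributes_nothing_to_hump(ages):
    # pure Gompertz data: the hump component should carry ~no deaths
    gS = 5e-5 * np.exp(0.1 * (ages - 10))
    e = np.full(ages.size, 1e7)
    fit = fit_sse(e * gS, e, ages=ages)
    assert fit.converged
    assert fit.hump_death_share < 1e-4


def test_toy_total_fit_matches_true_components(ages):
    hump, background = toy_components(DEFAULT_TOY)
    gH = np.sum(list(hump.values()), axis=0)
    gS = np.sum(list(background.values()), axis=0)
    e = np.full(ages.size, DEFAULT_TOY.exposure)
    fit = fit_sse(e * (gH + gS), e, ages=ages)
    assert fit.converged
    mu = gH + gS
    core = gH > 0.1 * mu
    assert np.max(np.abs(fit.gamma_H[core] / gH[core] - 1)) < 0.15


def test_exposure_scale_near_invariance(ages):
    # scaling deaths and exposures together multiplies the likelihood but
    # not the penalty, so invariance is only approximate: the total fit
    # and the core of each component must stay put
    gH, gS = two_component_truth(ages)
    mu = gH + gS
    e1 = np.full(ages.size, 1e6)
    f1 = fit_sse(e1 * mu, e1, ages=ages)
    f2 = fit_sse(3 * e1 * mu, 3 * e1, ages=ages)
    assert np.max(np.abs(f2.mu_hat / f1.mu_hat - 1)) < 0.01
    core = gH > 0.1 * mu
    assert np.max(np.abs(f2.gamma_H[core] / f1.gamma_H[core] - 1)) < 0.05


def test_input_validation(ages):
    e = np.full(ages.size, 1e5)
    with pytest.raises(ValueError, match="negative deaths"):
        fit_sse(-np.ones(ages.size), e, ages=ages)
    with pytest.raises(ValueError, match="exposures"):
        fit_sse(np.ones(ages.size), np.zeros(ages.size), ages=ages)


def test_select_lambdas_contract(ages):
    gH, gS = two_component_truth(ages)
    e = np.full(ages.size, 1e5)
    d = np.random.default_rng(9).poisson(e * (gH + gS)).astype(float)
    grid = [1e1, 1e3, 1e5]
    (lh, ls), fit = select_lambdas(d, e, grid=grid, ages=ages,
                                   return_fit=True)
    assert lh in grid and ls in grid
    assert fit.lambdas == (lh, ls)
    # the returned pair minimizes BIC on the grid
    for a in grid:
        for b in grid:
            other = fit_sse(d, e, penalties=default_penalties(a, b), ages=ages)
            assert fit.bic <= other.bic + 1e-6
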