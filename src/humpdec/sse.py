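"""All-cause sum-of-smooth-exponentials fit: hump + senescence.

The force of mortality over the truncated age range (default 10-90) is
modelled as mu = gamma_H + gamma_S where each component is a smooth
positive curve exp(X beta) on an equally spaced B-spline basis, and
observed deaths are Poisson with mean C gamma, C = [E : E] the composite
matrix that multiplies each component by the exposures and sums them.

Identifiability comes from shape, not from age windows: the senescence
component is constrained to be monotonically nondecreasing and the hump
component to be log-concave, via heavily weighted asymmetric difference
penalties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import PenaltyBundle, SplineBasis, bspline_basis, difference_matrix
from .pclm import PCLMResult, fit_pclm

__all__ = ["SSEFit", "fit_sse", "select_lambdas", "default_bases",
           "default_penalties", "initial_betas"]

DEFAULT_KNOT_SPACING = 2.0
DEFAULT_DEGREE = 3


@dataclass
class SSEFit:
    """Two-component all-cause fit and its diagnostics."""

    ages: np.ndarray
    gamma_H: np.ndarray     # hump rate component
    gamma_S: np.ndarray     # senescence rate component
    beta_H: np.ndarray
    beta_S: np.ndarray
    mu_hat: np.ndarray      # gamma_H + gamma_S
    dhat_H: np.ndarray      # expected hump deaths e * gamma_H
    dhat_S: np.ndarray      # expected senescence deaths e * gamma_S
    exposures: np.ndarray
    lambdas: tuple          # (lambda_H, lambda_S)
    deviance: float
    ed: float               # effective dimension
    bic: float
    converged: bool
    iterations: int
    max_shape_violation: float

    @property
    def hump_death_share(self) -> float:
        """Share of all expected deaths attributed to the hump component."""
        tot = self.dhat_H.sum() + self.dhat_S.sum()
        return float(self.dhat_H.sum() / tot) if tot > 0 else 0.0


def default_bases(ages, knot_spacing=DEFAULT_KNOT_SPACING,
                  degree=DEFAULT_DEGREE) -> tuple[SplineBasis, SplineBasis]:
    b = bspline_basis(np.asarray(ages, dtype=float), knot_spacing, degree)
    return b, b


def default_penalties(lambda_H=10.0, lambda_S=1e5, order_H=3, order_S=2,
                      shape_weight=1e6, ridge=1e-6):
    """Penalty pair for (hump, senescence).

    The hump penalty is order 3 (shrinks towards a log-quadratic, i.e.
    Gaussian-in-log bump); the senescence penalty is order 2 (shrinks
    towards a log-linear Gompertz line while still allowing a plateau).
    This asymmetry is what keeps the two components from trading mass:
    a heavily smoothed hump cannot absorb an exponential rise and a
    heavily smoothed senescence curve cannot absorb a bump.
    """
    return (
        PenaltyBundle(lam=lambda_H, order=order_H, shape="log_concave",
                      shape_weight=shape_weight, ridge=ridge,
                      ridge_center=-20.0),
        PenaltyBundle(lam=lambda_S, order=order_S, shape="monotone_increasing",
                      shape_weight=shape_weight, ridge=ridge),
    )


def initial_betas(deaths, exposures, bases, gompertz_from: float = 55.0):
    """Deterministic starting values placing each component in its basin.

    Senescence: a log-linear (Gompertz) fit on the old ages, extrapolated
    over the whole grid.  Hump: a light smooth of the log residual rate
    above that initial senescence curve.
    """
    basis_H, basis_S = bases
    ages = basis_S.ages
    rates = np.maximum(deaths / exposures, 1e-12)
    old = ages >= min(gompertz_from, ages[len(ages) // 2])
    A = np.column_stack([np.ones(old.sum()), ages[old]])
    coef, *_ = np.linalg.lstsq(A, np.log(rates[old]), rcond=None)
    gamma_S0 = np.exp(coef[0] + coef[1] * ages)
    gamma_S0 = np.minimum(gamma_S0, rates.max() * 2)

    def smooth_log(basis, logy):
        B = basis.B
        D = difference_matrix(basis.n_coef, 2)
        lhs = B.T @ B + 1.0 * D.T @ D + 1e-8 * np.eye(basis.n_coef)
        return np.linalg.solve(lhs, B.T @ logy)

    beta_S = smooth_log(basis_S, np.log(gamma_S0))
    resid = np.maximum(rates - gamma_S0, 1e-12)
    beta_H = smooth_log(basis_H, np.log(resid))
    return beta_H, beta_S


def fit_sse(deaths, exposures, bases=None, penalties=None, weights=None,
            ages=None, max_iter: int = 200, tol: float = 1e-6,
            shape_tol: float | None = 1e-9) -> SSEFit:
    """Penalized ML fit of d ~ Poisson(e*(gamma_H + gamma_S)).

    Parameters
    ----------
    deaths, exposures : vectors over the (truncated) age grid.
    bases : optional (basis_H, basis_S) pair; defaults to cubic B-splines
        with 2-year knot spacing on ``ages``.
    penalties : optional (PenaltyBundle_H, PenaltyBundle_S) pair; the
        hump bundle must be log_concave, the senescence bundle
        monotone_increasing (defaults enforce this).
    weights : optional per-age regression weights.
    """
    deaths = np.asarray(deaths, dtype=float)
    exposures = np.asarray(exposures, dtype=float)
    if np.any(deaths < 0):
        raise ValueError("negative deaths")
    if np.any(exposures <= 0):
        raise ValueError("nonpositive exposures")
    if ages is None:
        ages = np.arange(10, 10 + deaths.size)
    ages = np.asarray(ages, dtype=float)
    if bases is None:
        bases = default_bases(ages)
    if penalties is None:
        penalties = default_penalties()
    basis_H, basis_S = bases
    m = deaths.size

    # composite matrix [E : E]
    E = np.diag(exposures)
    C = np.hstack([E, E])

    beta0 = initial_betas(deaths, exposures, bases)
    res: PCLMResult = fit_pclm(
        deaths, C, [basis_H, basis_S], list(penalties), list(beta0),
        weights=weights, max_iter=max_iter, tol=tol, shape_tol=shape_tol,
    )
    gamma_H, gamma_S = res.gammas
    bic = res.deviance + np.log(m) * res.ed
    return SSEFit(
        ages=ages, gamma_H=gamma_H, gamma_S=gamma_S,
        beta_H=res.betas[0], beta_S=res.betas[1],
        mu_hat=gamma_H + gamma_S,
        dhat_H=exposures * gamma_H, dhat_S=exposures * gamma_S,
        exposures=exposures,
        lambdas=(penalties[0].lam, penalties[1].lam),
        deviance=res.deviance, ed=res.ed, bic=bic,
        converged=res.converged, iterations=res.iterations,
        max_shape_violation=res.max_shape_violation,
    )


def select_lambdas(deaths, exposures, bases=None, grid=None, ages=None,
                   return_fit: bool = False):
    """BIC grid search over (lambda_H, lambda_S).

    BIC = deviance + log(m) * effective dimension.  Deterministic
    tie-break towards the larger lambda pair (heavier smoothing).
    """
    if grid is None:
        grid = np.logspace(1, 6, 6)
    grid = np.sort(np.asarray(grid, dtype=float))
    best = None
    for lh in grid:
        for ls in grid:
            fit = fit_sse(deaths, exposures, bases=bases,
                          penalties=default_penalties(lh, ls), ages=ages)
            key = (fit.bic, -lh, -ls)
            if best is None or key < best[0]:
                best = (key, (lh, ls), fit)
    (lh, ls), fit = best[1], best[2]
    if return_fit:
        return (lh, ls), fit
    return lh, ls
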