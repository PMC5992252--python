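"""Constrained cause-deleted decomposition of the hump and senescence.

For each selected (hump-related) cause kappa, the two components are
re-estimated on cause-deleted death counts d^-kappa = d - d^kappa, and
the cause's contribution to each component is the drop it induces:

    delta_j^kappa = gamma_j_hat - gamma_j^-kappa,   j in {hump, senescence}.

Coherence with the all-cause fit is imposed by estimating all K
cause-deleted models *simultaneously*, subject to

    e * sum_k delta_H^kappa = dhat_H
    e * sum_k delta_S^kappa = dhat_S - d^nonhump,

where d^nonhump are the observed deaths from causes not selected
(entirely senescent by assumption).  Rewriting the constraints in the
unknowns turns each into a pseudo-observation block with response
(K-1) * dhat_j (+ d^nonhump for senescence) and mean e * sum_k
gamma_j^-kappa, appended to the Poisson regression with a large weight
(1e5) -- the data-augmentation device that replaces Lagrange multipliers.
The whole stacked system is still a composite link model and is fitted
with the same penalized IRLS as the all-cause model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .basis import PenaltyBundle, SplineBasis
from .pclm import fit_pclm
from .sse import SSEFit, default_bases, default_penalties
from .surface import RateSurface

__all__ = ["AugmentedSystem", "CauseDecomposition", "build_augmented_system",
           "fit_constrained", "decompose_causes", "single_cause_contribution",
           "contributions_summary"]

CONSTRAINT_WEIGHT = 1e5


@dataclass
class AugmentedSystem:
    """Stacked cause-deleted system with constraint pseudo-observations.

    response
        (d^-k1, ..., d^-kK, (K-1)*dhat_H, (K-1)*dhat_S + d^nonhump),
        length (K+2)*m.
    composite
        Sparse ((K+2)*m, 2*K*m) matrix: block-diagonal exposure blocks
        for the K cause-deleted data rows (hump and senescence columns),
        and two constraint block-rows summing the K per-cause components.
    reg_weights
        1 for data rows, the constraint weight for constraint rows.
    """

    response: np.ndarray
    composite: sp.csr_matrix
    reg_weights: np.ndarray
    K: int
    m: int
    hump_causes: list
    exposures: np.ndarray
    d_nonhump: np.ndarray
    constraint_weight: float = CONSTRAINT_WEIGHT


@dataclass
class CauseDecomposition:
    """Cause-deleted components and per-cause contributions."""

    ages: np.ndarray
    causes: list                       # the selected hump-related causes
    gamma_H_minus: dict                # cause -> cause-deleted hump curve
    gamma_S_minus: dict
    delta_H: dict                      # cause -> contribution to the hump
    delta_S: dict
    exposures: np.ndarray
    fit: SSEFit                        # the all-cause fit decomposed
    d_nonhump: np.ndarray
    constraint_residual_H: float       # relative L2 gap of the hump constraint
    constraint_residual_S: float
    converged: bool
    iterations: int
    max_shape_violation: float

    @property
    def sum_delta_H(self) -> np.ndarray:
        return np.sum([self.delta_H[c] for c in self.causes], axis=0)

    @property
    def sum_delta_S(self) -> np.ndarray:
        return np.sum([self.delta_S[c] for c in self.causes], axis=0)


def build_augmented_system(surface: RateSurface, fit: SSEFit, hump_causes,
                           year=None,
                           constraint_weight: float = CONSTRAINT_WEIGHT
                           ) -> AugmentedSystem:
    """Assemble the stacked constrained system for K >= 2 selected causes.

    The constraint multiplier is K - 1: summing the K cause-deleted
    identities e*gamma_j^-k = e*(gamma_j_hat - delta_j^k) and applying
    the sum constraint leaves (K-1) * dhat_j on the response side.
    """
    hump_causes = list(hump_causes)
    K = len(hump_causes)
    if K < 2:
        raise ValueError(
            "the augmented system needs at least 2 causes; "
            "use single_cause_contribution for K = 1"
        )
    missing = [c for c in hump_causes if c not in surface.causes]
    if missing:
        raise ValueError(f"causes not on the surface: {missing}")
    m = len(surface.ages)
    if len(fit.ages) != m or np.any(np.asarray(fit.ages) != surface.ages):
        raise ValueError("fit and surface age grids differ")

    e = surface.exposure(year)
    d_total = surface.total_deaths(year)
    d_cause = {c: surface.cause_deaths(c, year) for c in hump_causes}
    nonhump = [c for c in surface.nonstotal_causes if c not in hump_causes]
    d_nonhump = (np.sum([surface.cause_deaths(c, year) for c in nonhump], axis=0)
                 if nonhump else np.zeros(m))

    response = np.concatenate(
        [d_total - d_cause[c] for c in hump_causes]
        + [(K - 1) * fit.dhat_H, (K - 1) * fit.dhat_S + d_nonhump]
    )

    # columns: K hump blocks then K senescence blocks, each of length m
    E = sp.diags(e)
    Z = sp.csr_matrix((m, m))
    rows = []
    for k in range(K):
        blocks = [E if j == k else Z for j in range(K)]     # hump part
        blocks += [E if j == k else Z for j in range(K)]    # senescence part
        rows.append(sp.hstack(blocks))
    rows.append(sp.hstack([E] * K + [Z] * K))               # hump constraint
    rows.append(sp.hstack([Z] * K + [E] * K))               # senescence constraint
    composite = sp.csr_matrix(sp.vstack(rows))

    reg_weights = np.concatenate(
        [np.ones(K * m), np.full(2 * m, constraint_weight)]
    )
    return AugmentedSystem(
        response=response, composite=composite, reg_weights=reg_weights,
        K=K, m=m, hump_causes=hump_causes, exposures=e, d_nonhump=d_nonhump,
        constraint_weight=constraint_weight,
    )


def fit_constrained(system: AugmentedSystem, fit: SSEFit, bases=None,
                    penalties=None, max_iter: int = 300, tol: float = 1e-6,
                    shape_tol: float | None = 1e-9) -> CauseDecomposition:
    """Jointly fit the K cause-deleted two-component models.

    Bases, penalties (including the shape constraints) and smoothing
    weights default to those of the all-cause fit, so the deltas reflect
    cause removal rather than changed smoothness.
    """
    K, m = system.K, system.m
    if bases is None:
        bases = default_bases(fit.ages)
    if penalties is None:
        penalties = default_penalties(fit.lambdas[0], fit.lambdas[1])
    basis_H, basis_S = bases
    pen_H, pen_S = penalties

    # start each cause-deleted component at (K-1)/K of the all-cause fit,
    # the value implied by an equal split of the constraints
    shift = np.log((K - 1) / K)
    beta0 = [fit.beta_H + shift] * K + [fit.beta_S + shift] * K
    all_bases = [basis_H] * K + [basis_S] * K
    all_pens = [pen_H] * K + [pen_S] * K

    res = fit_pclm(system.response, system.composite, all_bases, all_pens,
                   beta0, weights=system.reg_weights, max_iter=max_iter,
                   tol=tol, shape_tol=shape_tol)

    causes = system.hump_causes
    gH = {c: res.gammas[k] for k, c in enumerate(causes)}
    gS = {c: res.gammas[K + k] for k, c in enumerate(causes)}
    dH = {c: fit.gamma_H - gH[c] for c in causes}
    dS = {c: fit.gamma_S - gS[c] for c in causes}

    e = system.exposures
    sum_dH = np.sum([dH[c] for c in causes], axis=0)
    sum_dS = np.sum([dS[c] for c in causes], axis=0)
    res_H = _rel_l2(e * sum_dH, fit.dhat_H)
    res_S = _rel_l2(e * sum_dS, fit.dhat_S - system.d_nonhump)
    if max(res_H, res_S) > 1e-2:
        gap = np.abs(e * sum_dH - fit.dhat_H)
        worst = np.asarray(fit.ages)[np.argsort(gap)[::-1][:3]]
        warnings.warn(
            "constraint residual exceeds 1e-2; worst ages "
            f"{sorted(int(a) for a in worst)}"
        )
    return CauseDecomposition(
        ages=fit.ages, causes=causes, gamma_H_minus=gH, gamma_S_minus=gS,
        delta_H=dH, delta_S=dS, exposures=e, fit=fit,
        d_nonhump=system.d_nonhump,
        constraint_residual_H=res_H, constraint_residual_S=res_S,
        converged=res.converged, iterations=res.iterations,
        max_shape_violation=res.max_shape_violation,
    )


def decompose_causes(surface: RateSurface, fit: SSEFit, hump_causes,
                     year=None, **kwargs) -> CauseDecomposition:
    """Convenience wrapper: build the augmented system and fit it."""
    system = build_augmented_system(surface, fit, hump_causes, year=year)
    return fit_constrained(system, fit, **kwargs)


def single_cause_contribution(surface: RateSurface, fit: SSEFit, cause: str,
                              year=None, bases=None, penalties=None):
    """K = 1 special case: one unconstrained refit on cause-deleted data.

    Returns (delta_H, delta_S) = (gamma_hat - gamma^-kappa) per component.
    With a single cause there is no sum constraint to impose.
    """
    from .sse import fit_sse

    if penalties is None:
        penalties = default_penalties(fit.lambdas[0], fit.lambdas[1])
    d_minus = surface.total_deaths(year) - surface.cause_deaths(cause, year)
    refit = fit_sse(d_minus, surface.exposure(year), bases=bases,
                    penalties=penalties, ages=fit.ages)
    return fit.gamma_H - refit.gamma_H, fit.gamma_S - refit.gamma_S


def contributions_summary(dec: CauseDecomposition) -> "pd.DataFrame":
    """Per-cause summary of the hump contributions.

    Columns: cause, hump_deaths (sum of e*delta_H), share, peak_age
    (argmax of delta_H; NaN for an all-zero contribution), and the
    quartile ages q25/q50/q75 of the delta_H death density.
    """
    import pandas as pd

    ages = np.asarray(dec.ages, dtype=float)
    rows = []
    totals = {c: float(np.sum(dec.exposures * dec.delta_H[c])) for c in dec.causes}
    grand = sum(totals.values())
    for c in dec.causes:
        delta = dec.delta_H[c]
        dens = np.maximum(dec.exposures * delta, 0.0)
        tot = dens.sum()
        if tot <= 0 or np.max(np.abs(delta)) < 1e-300:
            peak = q25 = q50 = q75 = float("nan")
        else:
            peak = float(ages[np.argmax(delta)])
            cum = np.cumsum(dens) / tot
            q25, q50, q75 = (float(np.interp(q, cum, ages)) for q in (0.25, 0.5, 0.75))
        rows.append({
            "cause": c,
            "hump_deaths": totals[c],
            "share": totals[c] / grand if grand > 0 else 0.0,
            "peak_age": peak,
            "q25": q25, "q50": q50, "q75": q75,
        })
    return pd.DataFrame(rows)


def _rel_l2(a, b) -> float:
    denom = float(np.linalg.norm(b))
    if denom == 0:
        return float(np.linalg.norm(a))
    return float(np.linalg.norm(a - b) / denom)
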