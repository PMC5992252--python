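"""Graduation of abridged-age death counts to single ages.

Cause-specific deaths are often reported in abridged age groups (0-4,
5-9, ...) while the decomposition needs single-age schedules.  Grouped
counts are modelled directly with a penalized composite-link Poisson
fit: expected group counts are G (E exp(X beta)) where G aggregates
single ages into groups, E holds single-age exposures and X is a cubic
B-spline basis with one knot per two years of age and a second-order
difference penalty.  The smoothing parameter is chosen per cause by BIC.
Graduated cause rates are finally rescaled multiplicatively at each age
so that they sum to a supplied single-age all-cause schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .basis import PenaltyBundle, bspline_basis, difference_matrix
from .pclm import fit_pclm

__all__ = ["AbridgedGroups", "graduate_counts", "rescale_to_total"]

ZERO_FLOOR = 1e-12


@dataclass
class AbridgedGroups:
    """Grouped death counts with single-age exposures.

    bounds
        Contiguous half-open integer (lower, upper) pairs tiling the
        target age range; "age x" means the interval [x, x+1), so a
        group (10, 15) covers single ages 10..14.
    counts
        Mapping cause -> nonnegative count per group (same order as
        bounds).
    single_age_exposures
        Positive person-years at each single age of the tiled range.
    """

    bounds: list
    counts: dict
    single_age_exposures: np.ndarray

    def __post_init__(self):
        self.single_age_exposures = np.asarray(self.single_age_exposures,
                                               dtype=float)
        if np.any(self.single_age_exposures <= 0):
            raise ValueError("nonpositive single-age exposure")
        lo0 = self.bounds[0][0]
        prev = lo0
        for lo, hi in self.bounds:
            if hi <= lo:
                raise ValueError(f"empty group ({lo}, {hi})")
            if lo != prev:
                raise ValueError(f"gap or overlap before group ({lo}, {hi})")
            prev = hi
        n_ages = prev - lo0
        if self.single_age_exposures.size != n_ages:
            raise ValueError(
                f"exposures cover {self.single_age_exposures.size} ages, "
                f"groups tile {n_ages}"
            )
        for c, y in self.counts.items():
            y = np.asarray(y, dtype=float)
            if y.size != len(self.bounds):
                raise ValueError(f"cause {c}: {y.size} counts for "
                                 f"{len(self.bounds)} groups")
            if np.any(y < 0):
                raise ValueError(f"cause {c}: negative count")
            self.counts[c] = y

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.bounds[0][0], self.bounds[-1][1])

    def grouping_matrix(self) -> np.ndarray:
        """G: (n_groups, n_ages) 0/1 aggregation matrix."""
        ages = self.ages
        G = np.zeros((len(self.bounds), ages.size))
        for g, (lo, hi) in enumerate(self.bounds):
            G[g, (ages >= lo) & (ages < hi)] = 1.0
        return G


def _graduate_one(y, C, basis, lam, beta0):
    pen = PenaltyBundle(lam=lam, order=2, shape="none")
    res = fit_pclm(y, C, [basis], [pen], [beta0])
    bic = res.deviance + np.log(y.size) * res.ed
    return res, bic


def graduate_counts(groups: AbridgedGroups, lambda_grid=None) -> dict:
    """Graduate each cause's grouped counts to single-age rates.

    Returns a dict cause -> rate vector on ``groups.ages``.  Smoothing
    is selected per cause by BIC over ``lambda_grid`` (default
    ``logspace(0, 6, 7)``), with ties broken towards heavier smoothing.
    An all-zero cause yields uniform near-zero rates (1e-12) with a
    warning.
    """
    if len(groups.bounds) < 4:
        raise ValueError("insufficient groups (need at least 4)")
    if lambda_grid is None:
        lambda_grid = np.logspace(0, 6, 7)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))
    if np.any(lambda_grid <= 0):
        raise ValueError("lambda_grid must be positive")

    ages = groups.ages.astype(float)
    e = groups.single_age_exposures
    G = groups.grouping_matrix()
    C = G @ np.diag(e)
    basis = bspline_basis(ages, knot_spacing=2.0, degree=3)

    out = {}
    for cause, y in groups.counts.items():
        if np.all(y == 0):
            warnings.warn(f"cause {cause!r}: all counts zero; "
                          "returning floor rates")
            out[cause] = np.full(ages.size, ZERO_FLOOR)
            continue
        # crude start: constant at the overall log rate, lightly shaped
        # by projecting the log group rates onto the basis
        grp_rate = np.maximum(y / (G @ e), ZERO_FLOOR)
        log_age = G.T @ np.log(grp_rate) / G.sum(axis=0)
        B = basis.B
        D = difference_matrix(basis.n_coef, 2)
        beta0 = np.linalg.solve(B.T @ B + D.T @ D + 1e-8 * np.eye(basis.n_coef),
                                B.T @ log_age)
        best = None
        for lam in lambda_grid:
            res, bic = _graduate_one(y, C, basis, lam, beta0)
            key = (bic, -lam)
            if best is None or key < best[0]:
                best = (key, res)
        out[cause] = best[1].gammas[0]
    return out


def rescale_to_total(cause_rates: dict, total_rates) -> dict:
    """Rescale cause rates at each age so they sum to the all-cause rate.

    All causes at age x are multiplied by total(x) / sum_k rate_k(x);
    after rescaling the sum equals ``total_rates`` exactly.  Ages where
    the cause-sum is zero but the total is not are an error.
    """
    total_rates = np.asarray(total_rates, dtype=float)
    causes = list(cause_rates)
    if not causes:
        raise ValueError("no causes")
    mat = np.vstack([np.asarray(cause_rates[c], dtype=float) for c in causes])
    if mat.shape[1] != total_rates.size:
        raise ValueError("cause and total rates on different age grids")
    s = mat.sum(axis=0)
    bad = np.flatnonzero((s == 0) & (total_rates > 0))
    if bad.size:
        raise ValueError(f"zero cause-sum at age indices {bad.tolist()} "
                         "with nonzero total")
    factor = np.where(s > 0, total_rates / np.where(s > 0, s, 1.0), 0.0)
    return {c: mat[i] * factor for i, c in enumerate(causes)}
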