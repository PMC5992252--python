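"""B-spline bases, roughness penalties and shape-constraint penalties.

All fitting modules share the same building blocks: equally spaced
B-spline design matrices, difference-matrix roughness penalties, and
asymmetric (iteratively reweighted) penalties that push the fitted
components towards a required shape -- a nondecreasing senescence curve
and a log-concave young-adult hump.

For equally spaced knots, nonnegative first differences of the
coefficients are sufficient for a nondecreasing fitted curve, and
nonpositive second differences are sufficient for concavity of the
log-curve; the shape penalties therefore act on coefficient differences,
not on the curve pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineBasis",
    "PenaltyBundle",
    "bspline_basis",
    "identity_basis",
    "difference_matrix",
    "shape_violation_penalty",
]

SHAPES = ("none", "monotone_increasing", "log_concave")


@dataclass
class SplineBasis:
    """Evaluated B-spline basis on an age grid.

    Attributes
    ----------
    ages : ndarray
        Evaluation grid (single ages).
    degree : int
        Spline degree (3 = cubic).
    knots : ndarray
        Full (extended) equally spaced knot sequence.
    B : ndarray, shape (len(ages), n_coef)
        Basis values; rows sum to one (partition of unity).
    """

    ages: np.ndarray
    degree: int
    knots: np.ndarray
    B: np.ndarray

    @property
    def n_coef(self) -> int:
        return self.B.shape[1]


def bspline_basis(ages, knot_spacing: float = 2.0, degree: int = 3) -> SplineBasis:
    """Equally spaced B-spline basis covering ``ages``.

    Follows the standard P-spline construction: the span is divided into
    ``ndx = ceil((max-min)/knot_spacing)`` intervals and the knot set is
    extended by ``degree`` knots on each side, giving ``ndx + degree``
    basis functions.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < degree + 2:
        raise ValueError("grid too short for requested degree")
    lo, hi = ages.min(), ages.max()
    span = hi - lo
    if knot_spacing > span:
        raise ValueError(
            f"knot_spacing {knot_spacing} exceeds grid span {span}"
        )
    ndx = int(np.ceil(span / knot_spacing))
    knots = lo + knot_spacing * np.arange(-degree, ndx + degree + 1)
    # clip the right edge into the last interval so the boundary age is
    # evaluated as the limit from the left
    x = np.minimum(ages, knots[-degree - 1] - 1e-9 * max(knot_spacing, 1.0))
    B = BSpline.design_matrix(x, knots, degree).toarray()
    return SplineBasis(ages=ages, degree=degree, knots=knots, B=B)


def identity_basis(ages) -> SplineBasis:
    """Degenerate basis with one coefficient per age (B = I).

    Coefficients are then the log rates themselves; used for tiny exact
    cross-checks of the fitting machinery.
    """
    ages = np.asarray(ages, dtype=float)
    m = ages.size
    return SplineBasis(ages=ages, degree=0, knots=np.append(ages, ages[-1] + 1),
                       B=np.eye(m))


def difference_matrix(n: int, order: int) -> np.ndarray:
    """Order-``order`` difference matrix of shape (n-order, n)."""
    if order < 0 or order >= n:
        raise ValueError("invalid difference order")
    D = np.eye(n)
    for _ in range(order):
        D = np.diff(D, axis=0)
    return D


def shape_violation_penalty(beta, shape: str, weight: float = 1e6) -> np.ndarray:
    """Asymmetric shape penalty matrix for the current coefficients.

    monotone_increasing
        ``weight * D1' V D1`` with V flagging negative first differences.
    log_concave
        ``weight * D2' V D2`` with V flagging positive second differences.

    Returns the zero matrix when the constraint is inactive.
    """
    beta = np.asarray(beta, dtype=float)
    n = beta.size
    if shape == "none":
        return np.zeros((n, n))
    if shape == "monotone_increasing":
        D = difference_matrix(n, 1)
        v = (D @ beta < 0).astype(float)
    elif shape == "log_concave":
        D = difference_matrix(n, 2)
        v = (D @ beta > 0).astype(float)
    else:
        raise ValueError(f"unknown shape tag: {shape!r}")
    if not v.any():
        return np.zeros((n, n))
    return weight * (D.T * v) @ D


@dataclass
class PenaltyBundle:
    """Roughness + shape penalty configuration for one component.

    lam
        Smoothness weight on order-``order`` coefficient differences.
    order
        Difference order of the roughness penalty (1, 2 or 3).
    shape
        "none", "monotone_increasing" (senescence) or "log_concave" (hump).
    shape_weight
        Weight of the asymmetric shape penalty (large => near-exact).
    ridge
        Tiny ridge on all coefficients for numerical stability.
    ridge_center
        Coefficient value the ridge shrinks towards.  A strongly
        negative center on the hump component resolves the flat
        likelihood direction in which a log-linear "hump" trades mass
        with an exponential senescence curve: absent information, mass
        defaults to senescence.
    """

    lam: float = 10.0
    order: int = 2
    shape: str = "none"
    shape_weight: float = 1e6
    ridge: float = 1e-6
    ridge_center: float = 0.0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.order not in (1, 2, 3):
            raise ValueError("difference order must be 1, 2 or 3")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape tag: {self.shape!r}")

    def base_matrix(self, n: int) -> np.ndarray:
        D = difference_matrix(n, self.order)
        return self.lam * D.T @ D + self.ridge * np.eye(n)

    def shape_matrix(self, beta) -> np.ndarray:
        return shape_violation_penalty(beta, self.shape, self.shape_weight)

    def full_matrix(self, beta) -> np.ndarray:
        """Hessian of the penalty at ``beta`` (asymmetric part linearized)."""
        return self.base_matrix(len(beta)) + self.shape_matrix(beta)

    def value(self, beta) -> float:
        """Exact penalty value 0.5 * (roughness + ridge + shape terms)."""
        beta = np.asarray(beta, dtype=float)
        n = beta.size
        D = difference_matrix(n, self.order)
        v = 0.5 * self.lam * float(np.sum((D @ beta) ** 2))
        v += 0.5 * self.ridge * float(np.sum((beta - self.ridge_center) ** 2))
        if self.shape == "monotone_increasing":
            d1 = difference_matrix(n, 1) @ beta
            v += 0.5 * self.shape_weight * float(np.sum(np.minimum(d1, 0.0) ** 2))
        elif self.shape == "log_concave":
            d2 = difference_matrix(n, 2) @ beta
            v += 0.5 * self.shape_weight * float(np.sum(np.maximum(d2, 0.0) ** 2))
        return v

    def grad(self, beta) -> np.ndarray:
        """Gradient of the penalty value at ``beta``."""
        beta = np.asarray(beta, dtype=float)
        n = beta.size
        D = difference_matrix(n, self.order)
        g = self.lam * D.T @ (D @ beta) + self.ridge * (beta - self.ridge_center)
        if self.shape == "monotone_increasing":
            D1 = difference_matrix(n, 1)
            g += self.shape_weight * D1.T @ np.minimum(D1 @ beta, 0.0)
        elif self.shape == "log_concave":
            D2 = difference_matrix(n, 2)
            g += self.shape_weight * D2.T @ np.maximum(D2 @ beta, 0.0)
        return g

    def shape_violation(self, beta) -> float:
        """Largest current violation of the shape condition (0 if none)."""
        beta = np.asarray(beta, dtype=float)
        if self.shape == "monotone_increasing":
            d = difference_matrix(beta.size, 1) @ beta
            return float(max(0.0, -(d.min(initial=0.0))))
        if self.shape == "log_concave":
            d = difference_matrix(beta.size, 2) @ beta
            return float(max(0.0, d.max(initial=0.0)))
        return 0.0
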