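"""Screening many causes of death for hump candidates.

Hump-contributing causes show a high level of change -- both positive
and negative -- in their force of mortality during young adulthood.
The screen compares the first difference over age of each cause-specific
force of mortality with the all-cause equivalent between ages 10 and 34,
summarized per year by the age-wise Euclidean distance

    Delta_j^kappa = sqrt( sum_x (rho_xj^kappa - rho_xj)^2 ),

where rho are first differences of the rates.  The cause x year distance
matrix is standardized and reduced to two dimensions by PCA for visual
review; a configurable rule proposes a flag set.

The default rule references an inert (null) cause: a cause with no deaths
sits at distance ||rho_j|| in every year, so causes whose standardized
distance profile stays close to that null profile carry no age-shape
information, while causes that pull the profile away from it shape the
all-cause schedule.  Flagging is never canonical -- scores are always
exported so the analyst can add or remove causes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .surface import TOTAL, RateSurface

__all__ = ["SelectionResult", "shape_distance", "pca_flag", "select_causes"]


@dataclass
class SelectionResult:
    distances: pd.DataFrame   # cause x year distance matrix
    scores: pd.DataFrame      # cause x (PC1, PC2)
    explained: np.ndarray     # variance fractions of the first two axes
    flagged: list             # proposed hump candidates, input order
    null_deviation: pd.Series | None = None  # per-cause rms deviation from null


def shape_distance(surface: RateSurface, age_window=(10, 34)) -> pd.DataFrame:
    """Cause x year matrix of first-difference shape distances.

    The returned frame carries the per-year norm of the all-cause first
    differences in ``attrs["rho_norm"]`` -- the distance at which an
    inert cause would sit.
    """
    lo, hi = age_window
    if hi - lo < 3:
        raise ValueError("age window shorter than 3 ages")
    if lo < surface.ages.min() or hi > surface.ages.max():
        raise ValueError("age window outside the surface's age range")
    sel = (surface.ages >= lo) & (surface.ages <= hi)
    causes = surface.nonstotal_causes
    rows = {}
    null = {}
    for j, yr in enumerate(surface.years):
        e = surface.exposures[sel, j]
        mu_all = surface.total_deaths(yr)[sel] / e
        rho = np.diff(mu_all)
        null[yr] = float(np.linalg.norm(rho))
        for c in causes:
            mu_c = surface.cause_deaths(c, yr)[sel] / e
            rho_c = np.diff(mu_c)
            rows.setdefault(c, {})[yr] = float(np.linalg.norm(rho_c - rho))
    dist = pd.DataFrame(rows).T.loc[causes]
    dist.attrs["rho_norm"] = pd.Series(null)
    return dist


def pca_flag(distances: pd.DataFrame, rule: str = "null_deviation",
             null_threshold: float = 0.75, k: float = 3.0,
             rho_norm: pd.Series | None = None) -> SelectionResult:
    """Reduce the distance matrix to 2-D PCA scores and propose flags.

    Year columns are standardized (zero mean, unit variance over causes);
    constant columns are dropped with a warning.  PCA treats causes as
    observations.  The PC sign convention is fixed by making the loading
    of the latest year nonnegative.

    Rules
    -----
    null_deviation (default)
        Flag causes whose standardized distance profile deviates from
        the inert-cause (null) profile by more than ``null_threshold``
        rms per year.  Requires ``rho_norm`` (attached automatically by
        :func:`shape_distance` via ``distances.attrs``).
    pca_norm
        Flag causes whose Euclidean norm in the (PC1, PC2) plane exceeds
        ``k`` times the median norm.
    """
    if distances.shape[0] < 3 or distances.shape[1] < 2:
        raise ValueError("need at least 3 causes and 2 years")
    if rho_norm is None:
        rho_norm = distances.attrs.get("rho_norm")

    X = distances.copy().astype(float)
    null_row = None
    if rho_norm is not None:
        null_row = pd.Series({yr: float(rho_norm[yr]) for yr in X.columns})

    sd = X.std(axis=0, ddof=0)
    const = sd.index[sd == 0.0]
    if len(const):
        warnings.warn(f"dropping constant year columns: {list(const)}")
        X = X.drop(columns=const)
        if null_row is not None:
            null_row = null_row.drop(index=const)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    Z = (X - mean) / sd
    if null_row is not None:
        znull = (null_row - mean) / sd

    n_comp = min(2, Z.shape[0] - 1, Z.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(Z.values)
    # sign convention: loading of the latest year nonnegative
    latest = Z.columns.get_loc(Z.columns[-1])
    for a in range(n_comp):
        if pca.components_[a, latest] < 0:
            pca.components_[a] *= -1
            scores[:, a] *= -1
    if n_comp < 2:
        scores = np.column_stack([scores, np.zeros(len(Z))])
    explained = np.zeros(2)
    explained[:n_comp] = pca.explained_variance_ratio_[:2]

    score_df = pd.DataFrame(scores[:, :2], index=X.index, columns=["PC1", "PC2"])

    if rule == "null_deviation":
        if null_row is None:
            raise ValueError(
                "null_deviation rule needs the all-cause rho norms; pass "
                "rho_norm or use the frame returned by shape_distance"
            )
        dev = np.sqrt(((Z - znull) ** 2).mean(axis=1))
        flagged = [c for c in X.index if dev[c] > null_threshold]
        null_dev = dev
    elif rule == "pca_norm":
        norms = np.linalg.norm(scores[:, :2], axis=1)
        med = np.median(norms)
        flagged = [c for c, nrm in zip(X.index, norms) if nrm > k * med]
        null_dev = None
    else:
        raise ValueError(f"unknown rule: {rule!r}")

    return SelectionResult(distances=distances, scores=score_df,
                           explained=explained, flagged=flagged,
                           null_deviation=null_dev)


def drawdown_zscores(surface: RateSurface, age_window=(10, 34)) -> pd.Series:
    """Significance of each cause's within-window mortality decline.

    Years are pooled (summed deaths and exposures) and, for each cause,
    the maximum drawdown ``max_{x<y} (mu_x - mu_y)`` of the pooled rate
    inside the window is compared with its Poisson standard error.  A
    hump cause rises and then falls, producing a large positive z; a
    monotone (Gompertz-type) cause only produces noise-level drawdowns
    -- its rise actively suppresses them.
    """
    lo, hi = age_window
    sel = (surface.ages >= lo) & (surface.ages <= hi)
    e_pool = surface.exposures[sel, :].sum(axis=1)
    z = {}
    for c in surface.nonstotal_causes:
        d_pool = surface.deaths[sel, :, surface.causes.index(c)].sum(axis=1)
        mu = d_pool / e_pool
        var = np.maximum(d_pool, 1.0) / e_pool ** 2  # Var(mu_hat), floor 1 death
        best = 0.0
        run_max, run_var = mu[0], var[0]
        for x in range(1, mu.size):
            zx = (run_max - mu[x]) / np.sqrt(run_var + var[x])
            best = max(best, zx)
            if mu[x] > run_max:
                run_max, run_var = mu[x], var[x]
        z[c] = float(best)
    return pd.Series(z)


def select_causes(surface: RateSurface, age_window=(10, 34),
                  rule: str = "drawdown", z_crit: float = 6.0,
                  **flag_kwargs) -> SelectionResult:
    """Full screen: shape distances, PCA scores, and a proposed flag set.

    The default ``drawdown`` rule flags causes whose pooled death rate
    shows a statistically significant decline inside the window
    (``z > z_crit``) -- the operational form of "a high level of change,
    both positive and negative, during young adulthood".  The matrix
    rules of :func:`pca_flag` are available via ``rule=``.
    """
    dist = shape_distance(surface, age_window)
    if rule == "drawdown":
        res = pca_flag(dist, rule="null_deviation", null_threshold=np.inf)
        z = drawdown_zscores(surface, age_window)
        res.flagged = [c for c in dist.index if z[c] > z_crit]
        res.null_deviation = z
        return res
    return pca_flag(dist, rule=rule, **flag_kwargs)
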