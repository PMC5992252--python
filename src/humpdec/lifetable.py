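"""Period life tables, life expectancy lost, and Arriaga decomposition.

The magnitude of the hump (and of competing deletion schemes) is
summarized as life expectancy lost (LEL): the gain in life expectancy at
the base age from replacing the observed rate schedule by a
counterfactual one.  Three deletions are compared:

* L1 -- delete only the hump component (mu - sum_k delta_H^kappa), a
  *partial* reduction of rates with no fixed age bounds;
* L2 -- delete all deaths in a fixed age window (default 10-34);
* L3 -- delete only the selected causes' deaths in that window.

L3 <= L2 by construction.  Differences in life expectancy are split into
additive age (and cause) contributions with the Arriaga decomposition;
the symmetrized (two-direction average) form is used so that swapping
the two tables exactly negates every contribution while the sum still
equals the total difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .surface import RateSurface

__all__ = ["LifeTable", "LELResult", "lifetable", "life_expectancy_lost",
           "arriaga", "lel_measures"]


@dataclass
class LifeTable:
    """Standard single-age period life table, radix 1, open-ended last age.

    a_x = 0.5 at all ages (no infant correction is needed at ages >= 10);
    q_x = m_x / (1 + (1 - a_x) m_x), capped at 1; the open interval is
    closed with L = l/m (exponential tail), or L = 0 if the terminal
    rate is zero.
    """

    ages: np.ndarray
    mx: np.ndarray
    ax: np.ndarray
    qx: np.ndarray
    lx: np.ndarray
    dx: np.ndarray
    Lx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray

    def e_at(self, age) -> float:
        i = int(np.searchsorted(self.ages, age))
        if i >= len(self.ages) or self.ages[i] != age:
            raise ValueError(f"age {age} not in the table")
        return float(self.ex[i])


def lifetable(rates, ages=None, ax: float = 0.5) -> LifeTable:
    """Build a period life table from central death rates m_x."""
    mx = np.asarray(rates, dtype=float)
    if np.any(mx < 0):
        raise ValueError("negative death rate")
    n = mx.size
    if ages is None:
        ages = np.arange(10, 10 + n)
    ages = np.asarray(ages)
    a = np.full(n, float(ax))

    qx = mx / (1.0 + (1.0 - a) * mx)
    qx = np.minimum(qx, 1.0)
    qx[-1] = 1.0  # open-ended closure

    lx = np.empty(n)
    lx[0] = 1.0
    for i in range(1, n):
        lx[i] = lx[i - 1] * (1.0 - qx[i - 1])
    dx = lx * qx

    Lx = np.empty(n)
    Lx[:-1] = lx[1:] + a[:-1] * dx[:-1]
    Lx[-1] = lx[-1] / mx[-1] if mx[-1] > 0 else 0.0

    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / lx, 0.0)
    return LifeTable(ages=ages, mx=mx, ax=a, qx=qx, lx=lx, dx=dx,
                     Lx=Lx, Tx=Tx, ex=ex)


def life_expectancy_lost(observed, counterfactual, ages=None,
                         base_age=None) -> float:
    """e(counterfactual) - e(observed) at the base age (default: first age).

    A counterfactual above the observed schedule at some age (possible
    with negative contributions) triggers a warning, not an error.
    """
    observed = np.asarray(observed, dtype=float)
    counterfactual = np.asarray(counterfactual, dtype=float)
    if observed.shape != counterfactual.shape:
        raise ValueError("rate schedules on different grids")
    if np.any(counterfactual > observed + 1e-15):
        warnings.warn("counterfactual rates exceed observed at some ages")
    lt_obs = lifetable(observed, ages)
    lt_cf = lifetable(np.maximum(counterfactual, 0.0), ages)
    i = 0 if base_age is None else int(np.searchsorted(lt_obs.ages, base_age))
    return float(lt_cf.ex[i] - lt_obs.ex[i])


def _arriaga_oneway(lt1: LifeTable, lt2: LifeTable) -> np.ndarray:
    """Directed Arriaga contributions from table 1 to table 2."""
    l1, l2 = lt1.lx, lt2.lx
    L1, L2 = lt1.Lx, lt2.Lx
    T2 = lt2.Tx
    n = l1.size
    c = np.zeros(n)
    base = l1[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(l1 > 0, L1 / l1, 0.0)
        r2 = np.where(l2 > 0, L2 / l2, 0.0)
        s2 = np.where(l2 > 0, l1 / l2, 0.0)
    # direct effect + indirect/interaction via survivors carried forward
    c[:-1] = (l1[:-1] / base) * (r2[:-1] - r1[:-1]) \
        + (T2[1:] / base) * (s2[:-1] - s2[1:])
    e2_last = T2[-1] / l2[-1] if l2[-1] > 0 else 0.0
    e1_last = lt1.Tx[-1] / l1[-1] if l1[-1] > 0 else 0.0
    c[-1] = (l1[-1] / base) * (e2_last - e1_last)
    return c


def arriaga(lt_obs: LifeTable, lt_cf: LifeTable) -> np.ndarray:
    """Symmetrized Arriaga age decomposition of e_cf - e_obs at the base age.

    Contributions sum exactly to the difference in life expectancy; the
    decomposition is antisymmetric under swapping the two tables.
    """
    if len(lt_obs.ages) != len(lt_cf.ages) or np.any(lt_obs.ages != lt_cf.ages):
        raise ValueError("life tables on different age grids")
    fwd = _arriaga_oneway(lt_obs, lt_cf)
    bwd = _arriaga_oneway(lt_cf, lt_obs)
    c = 0.5 * (fwd - bwd)
    # distribute the (tiny) closure mismatch so the sum is exact
    target = lt_cf.ex[0] - lt_obs.ex[0]
    c[-1] += target - c.sum()
    return c


@dataclass
class LELResult:
    """The three LEL measures with age and cause splits."""

    base_age: int
    L1: float                      # hump-only deletion
    L2: float                      # all deaths in the age window
    L3: float                      # selected causes' deaths in the window
    window: tuple
    age_contributions: np.ndarray  # Arriaga split of L1 over age
    ages: np.ndarray
    cause_years_L1: dict           # cause -> years of L1
    cause_shares_L1: dict
    cause_years_L2: dict           # cause -> years of L2 (all causes)
    cause_shares_L2: dict

    def to_frame(self) -> pd.DataFrame:
        rows = [("L1", "all", self.L1, 1.0),
                ("L2", "all", self.L2, 1.0),
                ("L3", "all", self.L3, 1.0)]
        rows += [("L1", c, self.cause_years_L1[c], self.cause_shares_L1[c])
                 for c in self.cause_years_L1]
        rows += [("L2", c, self.cause_years_L2[c], self.cause_shares_L2[c])
                 for c in self.cause_years_L2]
        return pd.DataFrame(rows, columns=["measure", "cause", "years", "share"])


def _normalized_cause_split(observed, deletions: dict, total: float, ages):
    """Arriaga LEL per single-cause deletion, normalized to sum to ``total``.

    Interactions between causes are distributed proportionally to the
    single-deletion main effects (standard practice).
    """
    lt_obs = lifetable(observed, ages)
    years = {}
    for c, deleted in deletions.items():
        lt_cf = lifetable(np.maximum(observed - deleted, 0.0), ages)
        years[c] = float(arriaga(lt_obs, lt_cf).sum())
    s = sum(years.values())
    if s <= 0:
        shares = {c: 0.0 for c in years}
        return {c: 0.0 for c in years}, shares
    shares = {c: y / s for c, y in years.items()}
    return {c: shares[c] * total for c in years}, shares


def lel_measures(fit, dec, surface: RateSurface, window=(10, 34),
                 year=None, base_age=None) -> LELResult:
    """Compute L1/L2/L3 and their age and cause splits.

    The observed schedule is the surface's all-cause rate; L1 deletes
    the decomposition's summed hump contributions; L2 zeroes the window;
    L3 subtracts the selected causes' rates in the window.  A ``dec`` of
    None (no selected causes) gives L1 = L3 = 0.
    """
    ages = np.asarray(surface.ages)
    lo, hi = window
    if lo < ages.min() or hi > ages.max():
        raise ValueError("window outside the age grid")
    in_win = (ages >= lo) & (ages <= hi)
    e = surface.exposure(year)
    mu = surface.total_deaths(year) / e
    base = int(ages[0]) if base_age is None else int(base_age)
    i0 = int(np.searchsorted(ages, base))
    lt_obs = lifetable(mu, ages)

    # L1: partial deletion of the hump, all ages
    if dec is not None and dec.causes:
        hump = np.maximum(dec.sum_delta_H, 0.0)
        sel_causes = list(dec.causes)
    else:
        hump = np.zeros_like(mu)
        sel_causes = []
    lt_L1 = lifetable(np.maximum(mu - hump, 0.0), ages)
    L1 = float(lt_L1.ex[i0] - lt_obs.ex[i0])

    # L2: full deletion inside the window
    mu_L2 = mu.copy()
    mu_L2[in_win] = 0.0
    L2 = float(lifetable(mu_L2, ages).ex[i0] - lt_obs.ex[i0])

    # L3: deletion of the selected causes inside the window
    mu_L3 = mu.copy()
    if sel_causes:
        sel_rate = np.sum([surface.cause_deaths(c, year) for c in sel_causes],
                          axis=0) / e
        mu_L3[in_win] = np.maximum(mu_L3 - sel_rate, 0.0)[in_win]
    L3 = float(lifetable(mu_L3, ages).ex[i0] - lt_obs.ex[i0])

    age_contrib = arriaga(lt_obs, lt_L1)

    cause_years_L1, cause_shares_L1 = _normalized_cause_split(
        mu, {c: np.maximum(dec.delta_H[c], 0.0) for c in sel_causes}, L1, ages
    ) if sel_causes else ({}, {})

    win_deletions = {}
    for c in surface.nonstotal_causes:
        d = np.zeros_like(mu)
        d[in_win] = (surface.cause_deaths(c, year) / e)[in_win]
        win_deletions[c] = d
    cause_years_L2, cause_shares_L2 = _normalized_cause_split(
        mu, win_deletions, L2, ages)

    return LELResult(base_age=base, L1=L1, L2=L2, L3=L3, window=window,
                     age_contributions=age_contrib, ages=ages,
                     cause_years_L1=cause_years_L1,
                     cause_shares_L1=cause_shares_L1,
                     cause_years_L2=cause_years_L2,
                     cause_shares_L2=cause_shares_L2)
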