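"""Four-cause reference simulation with known ground truth.

The generator emulates a stylized cause-of-death landscape in which the
young adult mortality hump can be decomposed exactly, because every
cause's hump and senescence parts are known:

* cause A -- a marked but modest hump in the early twenties, near-zero
  intensity elsewhere;
* cause B -- a higher and much wider hump, levelling off to a stable
  plateau after age 40;
* cause C -- a hump combined with a Gompertz trend, the leading cause of
  death in the teens;
* cause D -- a pure Gompertz cause with no hump, the leading cause of
  death from the late twenties onwards and everywhere above cause A.

Functional forms per cause: a log-Gaussian hump
``h * exp(-(x - p)^2 / (2 s^2))``, a plateau ``c / (1 + exp(-(x - x0)/w))``
(logistic ramp), and a senescence term ``b * exp(theta (x - x_min))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .surface import TOTAL, RateSurface

__all__ = ["CauseParams", "ToyParams", "toy_rates", "toy_components",
           "sample_deaths", "multi_year_surface", "DEFAULT_TOY"]


@dataclass(frozen=True)
class CauseParams:
    """Generating parameters for one cause of death.

    hump_height/location/width parameterize the log-Gaussian bump;
    plateau_level a logistic ramp centred at plateau_onset;
    gompertz_level/slope the senescence term anchored at the grid start.
    """

    hump_height: float = 0.0
    hump_location: float = 22.0
    hump_width: float = 5.0
    plateau_level: float = 0.0
    plateau_onset: float = 35.0
    plateau_ramp: float = 3.0
    gompertz_level: float = 0.0
    gompertz_slope: float = 0.09
    floor: float = 1e-6


@dataclass(frozen=True)
class ToyParams:
    """Global configuration of the reference simulation."""

    causes: dict = field(default_factory=dict)
    age_min: int = 10
    age_max: int = 90
    exposure: float = 1e5
    seed: int = 0

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_min, self.age_max + 1)


DEFAULT_TOY = ToyParams(causes={
    "A": CauseParams(hump_height=2.5e-4, hump_location=21.0, hump_width=4.5,
                     floor=2e-6),
    "B": CauseParams(hump_height=6.0e-4, hump_location=24.0, hump_width=7.0,
                     plateau_level=1.0e-4, plateau_onset=35.0, floor=2e-6),
    "C": CauseParams(hump_height=7.0e-4, hump_location=18.0, hump_width=3.5,
                     gompertz_level=6.0e-5, gompertz_slope=0.08, floor=0.0),
    "D": CauseParams(gompertz_level=1.5e-4, gompertz_slope=0.09, floor=0.0),
})


def _check(params: ToyParams) -> None:
    for name, cp in params.causes.items():
        for f in ("hump_height", "plateau_level", "gompertz_level", "floor"):
            if getattr(cp, f) < 0:
                raise ValueError(f"cause {name}: {f} must be nonnegative")
        if cp.hump_width <= 0:
            raise ValueError(f"cause {name}: hump_width must be positive")


def cause_hump(cp: CauseParams, ages) -> np.ndarray:
    """The hump part of one cause's rate schedule."""
    x = np.asarray(ages, dtype=float)
    return cp.hump_height * np.exp(-((x - cp.hump_location) ** 2)
                                   / (2 * cp.hump_width ** 2))


def cause_background(cp: CauseParams, ages, age_min) -> np.ndarray:
    """Plateau + Gompertz + floor: everything that is not hump."""
    x = np.asarray(ages, dtype=float)
    plateau = cp.plateau_level / (1.0 + np.exp(-(x - cp.plateau_onset) / cp.plateau_ramp))
    gomp = cp.gompertz_level * np.exp(cp.gompertz_slope * (x - age_min))
    return plateau + gomp + cp.floor


def toy_components(params: ToyParams = DEFAULT_TOY):
    """Per-cause (hump, background) true schedules as dicts of arrays."""
    _check(params)
    ages = params.ages
    hump = {c: cause_hump(cp, ages) for c, cp in params.causes.items()}
    background = {c: cause_background(cp, ages, params.age_min)
                  for c, cp in params.causes.items()}
    return hump, background


def toy_rates(params: ToyParams = DEFAULT_TOY) -> dict:
    """True per-cause rate schedules (hump + background) over the grid."""
    hump, background = toy_components(params)
    return {c: hump[c] + background[c] for c in params.causes}


def sample_deaths(rates: dict, exposure, seed=None, ages=None,
                  year: int = 2000, noiseless: bool = False) -> RateSurface:
    """Draw a one-year surface of Poisson deaths from true rate schedules.

    With ``noiseless=True`` the expected counts are returned exactly.
    A "total" slice (sum over causes) is always included.
    """
    causes = list(rates)
    m = len(next(iter(rates.values())))
    if ages is None:
        ages = np.arange(10, 10 + m)
    e = np.broadcast_to(np.asarray(exposure, dtype=float), (m,)).copy()
    if np.any(e <= 0):
        raise ValueError("exposure must be positive")
    expect = np.column_stack([e * rates[c] for c in causes])
    if noiseless:
        deaths = expect
    else:
        rng = np.random.default_rng(seed)
        deaths = rng.poisson(expect).astype(float)
    deaths = np.concatenate([deaths, deaths.sum(axis=1, keepdims=True)], axis=1)
    return RateSurface(
        ages=ages, years=np.array([year]), causes=causes + [TOTAL],
        deaths=deaths[:, None, :], exposures=e[:, None],
    )


def multi_year_surface(params: ToyParams = DEFAULT_TOY, n_years: int = 20,
                       first_year: int = 1990, trend: float = 0.3,
                       seed=None, noiseless: bool = False) -> RateSurface:
    """Multi-year toy surface with smoothly drifting hump heights.

    Hump heights follow a cosine trend of relative amplitude ``trend``
    across the period (different phase per cause), emulating the slow
    period change in young adult excess mortality that the screening
    step must be robust to.
    """
    _check(params)
    ages = params.ages
    years = np.arange(first_year, first_year + n_years)
    causes = list(params.causes)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    m, J, K = len(ages), n_years, len(causes)
    deaths = np.zeros((m, J, K + 1))
    exposures = np.tile(np.broadcast_to(params.exposure, (m,)).astype(float)[:, None],
                        (1, J))
    for j in range(J):
        phase = 2 * np.pi * (j / max(J - 1, 1))
        expect = np.zeros((m, K))
        for k, c in enumerate(causes):
            cp = params.causes[c]
            factor = 1.0 + trend * np.cos(phase + k * np.pi / 2)
            cp_j = replace(cp, hump_height=cp.hump_height * factor)
            rate = cause_hump(cp_j, ages) + cause_background(cp_j, ages, params.age_min)
            expect[:, k] = exposures[:, j] * rate
        deaths[:, j, :K] = expect if noiseless else rng.poisson(expect)
        deaths[:, j, K] = deaths[:, j, :K].sum(axis=1)
    return RateSurface(ages=ages, years=years, causes=causes + [TOTAL],
                       deaths=deaths, exposures=exposures)
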