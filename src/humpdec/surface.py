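"""The RateSurface container and CSV input/output.

All pipeline stages consume and produce one structure: death counts and
population exposures on an age x year x cause grid.  Files are plain
long-format CSV with one row per (age, year, cause) cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RateSurface", "read_surface", "write_surface", "write_results"]

TOTAL = "total"
_FLOAT_FMT = "%.12g"  # 12 significant digits in every CSV


@dataclass
class RateSurface:
    """Deaths and exposures on an age x year x cause grid.

    deaths is indexed [age, year, cause]; exposures [age, year].  One
    cause label may be reserved as ``"total"``; when present it must
    equal the sum over the other causes.  Death counts are real-valued
    (graduated counts need not be integers).
    """

    ages: np.ndarray
    years: np.ndarray
    causes: list
    deaths: np.ndarray
    exposures: np.ndarray
    abridged: bool = False
    bounds: list = field(default_factory=list)  # (lo, hi) pairs if abridged

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.exposures = np.asarray(self.exposures, dtype=float)
        self.causes = list(self.causes)
        if self.deaths.shape != (len(self.ages), len(self.years), len(self.causes)):
            raise ValueError("deaths array shape does not match grid")
        if self.exposures.shape != (len(self.ages), len(self.years)):
            raise ValueError("exposures array shape does not match grid")
        if not self.abridged and len(self.ages) > 1 and np.any(np.diff(self.ages) != 1):
            raise ValueError("ages must be contiguous single years")
        if np.any(self.exposures <= 0):
            raise ValueError("exposures must be strictly positive")
        if np.any(self.deaths < 0):
            raise ValueError("deaths must be nonnegative")
        if TOTAL in self.causes:
            k = self.causes.index(TOTAL)
            others = [i for i in range(len(self.causes)) if i != k]
            tot = self.deaths[:, :, others].sum(axis=2)
            ref = self.deaths[:, :, k]
            scale = np.maximum(np.abs(ref), 1.0)
            if np.any(np.abs(tot - ref) > 1e-9 * scale):
                raise ValueError("cause-specific deaths do not sum to the total slice")

    @property
    def nonstotal_causes(self) -> list:
        return [c for c in self.causes if c != TOTAL]

    def cause_deaths(self, cause: str, year=None) -> np.ndarray:
        """Deaths for one cause; a single year (default: only year)."""
        j = self._year_index(year)
        return self.deaths[:, j, self.causes.index(cause)]

    def total_deaths(self, year=None) -> np.ndarray:
        j = self._year_index(year)
        if TOTAL in self.causes:
            return self.deaths[:, j, self.causes.index(TOTAL)]
        return self.deaths[:, j, :].sum(axis=1)

    def exposure(self, year=None) -> np.ndarray:
        return self.exposures[:, self._year_index(year)]

    def rates(self, cause=None, year=None) -> np.ndarray:
        """Central death rates deaths/exposure for one cause (or total)."""
        d = self.total_deaths(year) if cause in (None, TOTAL) else self.cause_deaths(cause, year)
        return d / self.exposure(year)

    def _year_index(self, year) -> int:
        if year is None:
            if len(self.years) != 1:
                raise ValueError("year must be given for a multi-year surface")
            return 0
        idx = np.where(self.years == year)[0]
        if idx.size == 0:
            raise ValueError(f"year {year} not on the surface")
        return int(idx[0])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.ages):
            for j, yr in enumerate(self.years):
                for k, c in enumerate(self.causes):
                    rows.append((a, yr, c, self.deaths[i, j, k], self.exposures[i, j]))
        return pd.DataFrame(rows, columns=["age", "year", "cause", "deaths", "exposure"])


def read_surface(path, layout: dict | None = None) -> RateSurface:
    """Read a long-format CSV into a dense RateSurface.

    Expected columns: age, year, cause, deaths, exposure (or, for
    abridged input flagged via ``layout={"abridged": True}``: age_lower,
    age_upper instead of age).  Every (age, year, cause) cell must be
    present exactly once.
    """
    layout = layout or {}
    abridged = bool(layout.get("abridged", False))
    df = pd.read_csv(path)
    agecol = "age_lower" if abridged else "age"
    required = {agecol, "year", "cause", "deaths", "exposure"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    dup = df.duplicated(subset=[agecol, "year", "cause"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValueError(
            f"duplicate cell (age={r[agecol]}, year={r['year']}, cause={r['cause']})"
        )
    bad = df.index[df["deaths"] < 0]
    if len(bad):
        raise ValueError(f"negative deaths at row {bad[0] + 2}")  # 1-based + header
    bad = df.index[df["exposure"] <= 0]
    if len(bad):
        raise ValueError(f"nonpositive exposure at row {bad[0] + 2}")

    ages = np.sort(df[agecol].unique())
    years = np.sort(df["year"].unique())
    causes = list(pd.unique(df["cause"]))
    full = len(ages) * len(years) * len(causes)
    if len(df) != full:
        have = set(zip(df[agecol], df["year"], df["cause"]))
        for a in ages:
            for yr in years:
                for c in causes:
                    if (a, yr, c) not in have:
                        raise ValueError(
                            f"missing cell (age={a}, year={yr}, cause={c})"
                        )
    ai = {a: i for i, a in enumerate(ages)}
    yi = {y: j for j, y in enumerate(years)}
    ci = {c: k for k, c in enumerate(causes)}
    deaths = np.zeros((len(ages), len(years), len(causes)))
    exposures = np.zeros((len(ages), len(years)))
    for row in df.itertuples(index=False):
        i, j, k = ai[getattr(row, agecol)], yi[row.year], ci[row.cause]
        deaths[i, j, k] = row.deaths
        exposures[i, j] = row.exposure
    bounds = []
    if abridged:
        bounds = [(int(a), int(df.loc[df[agecol] == a, "age_upper"].iloc[0]))
                  for a in ages]
    return RateSurface(ages=ages, years=years, causes=causes, deaths=deaths,
                       exposures=exposures, abridged=abridged, bounds=bounds)


def write_surface(surface: RateSurface, path) -> None:
    """Write a surface to long-format CSV (12 significant digits)."""
    surface.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_results(fit, dec, lel, out_dir) -> list:
    """Write the standard output set of the pipeline.

    components.csv    age, component, rate          (all-cause fit)
    contributions.csv age, cause, component, delta  (decomposition)
    lel.csv           measure, cause, years, share  (life expectancy lost)
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ages = np.asarray(fit.ages)
    if dec is not None:
        if not dec.causes:
            raise ValueError("no causes in the decomposition")
        if len(dec.ages) != len(ages) or np.any(np.asarray(dec.ages) != ages):
            raise ValueError("mismatched age grids between fit and decomposition")

    comp = pd.DataFrame({
        "age": np.tile(ages, 2),
        "component": ["hump"] * len(ages) + ["senescence"] * len(ages),
        "rate": np.concatenate([fit.gamma_H, fit.gamma_S]),
    })
    paths = [out / "components.csv"]
    comp.to_csv(paths[0], index=False, float_format=_FLOAT_FMT)

    if dec is not None:
        rows = []
        for c in dec.causes:
            for comp_name, delta in (("hump", dec.delta_H[c]),
                                     ("senescence", dec.delta_S[c])):
                for a, v in zip(ages, delta):
                    rows.append((a, c, comp_name, v))
        contrib = pd.DataFrame(rows, columns=["age", "cause", "component", "delta"])
        p = out / "contributions.csv"
        contrib.to_csv(p, index=False, float_format=_FLOAT_FMT)
        paths.append(p)

    if lel is not None:
        p = out / "lel.csv"
        lel.to_frame().to_csv(p, index=False, float_format=_FLOAT_FMT)
        paths.append(p)
    return paths
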