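import numpy as np
import pytest

from humpdec import (DEFAULT_TOY, CauseParams, ToyParams, multi_year_surface,
                     sample_deaths, toy_components, toy_rates)


def test_reference_landscape_orderings():
    """The qualitative cause orderings of the reference four-cause toy."""
    rates = toy_rates(DEFAULT_TOY)
    ages = DEFAULT_TOY.ages

    def at(c, lo, hi):
        sel = (ages >= lo) & (ages <= hi)
        return rates[c][sel]

    # C leads in the teens, B in the early-to-mid twenties, D at older ages
    assert np.all(at("C", 13, 20) >= np.max(
        [at("A", 13, 20), at("B", 13, 20), at("D", 13, 20)], axis=0))
    assert np.all(at("B", 22, 25) >= np.max(
        [at("A", 22, 25), at("C", 22, 25), at("D", 22, 25)], axis=0))
    assert np.all(at("D", 30, 90) >= np.max(
        [at("A", 30, 90), at("C", 30, 90)], axis=0))
    # D (pure Gompertz) dominates A (small pure hump) everywhere
    assert np.all(rates["D"] > rates["A"])
    # B's hump is higher and wider than A's
    hump, _ = toy_components(DEFAULT_TOY)
    assert hump["B"].max() > hump["A"].max()
    widthB = np.sum(hump["B"] > 0.5 * hump["B"].max())
    widthA = np.sum(hump["A"] > 0.5 * hump["A"].max())
    assert widthB > widthA


def test_total_log_rate_has_hump_shape():
    # the all-cause log rate falls, rises through a convex onset: exactly
    # two sign changes of its slope over the grid
    rates = toy_rates(DEFAULT_TOY)
    total = np.sum(list(rates.values()), axis=0)
    slope_sign = np.sign(np.diff(np.log(total)))
    changes = np.sum(np.diff(slope_sign) != 0)
    assert changes == 2


def test_sample_deaths_poisson_moments():
    rates = toy_rates(DEFAULT_TOY)
    mean = {c: r * DEFAULT_TOY.exposure for c, r in rates.items()}
    reps = [sample_deaths(rates, DEFAULT_TOY.exposure, seed=s)
            for s in range(40)]
    for c in ("B", "D"):
        k = reps[0].causes.index(c)
        draws = np.stack([r.deaths[:, 0, k] for r in reps])
        sel = mean[c] > 50  # enough counts for a stable z-test
        z = (draws.mean(axis=0) - mean[c]) / np.sqrt(mean[c] / len(reps))
        assert np.max(np.abs(z[sel])) < 5.0


def test_noiseless_equals_expectation():
    rates = toy_rates(DEFAULT_TOY)
    surf = sample_deaths(rates, DEFAULT_TOY.exposure, noiseless=True)
    for c, r in rates.items():
        assert np.allclose(surf.cause_deaths(c), r * DEFAULT_TOY.exposure)


def test_seed_reproducibility():
    rates = toy_rates(DEFAULT_TOY)
    a = sample_deaths(rates, DEFAULT_TOY.exposure, seed=11)
    b = sample_deaths(rates, DEFAULT_TOY.exposure, seed=11)
    c = sample_deaths(rates, DEFAULT_TOY.exposure, seed=12)
    assert np.array_equal(a.deaths, b.deaths)
    assert not np.array_equal(a.deaths, c.deaths)


def test_multi_year_surface_structure():
    surf = multi_year_surface(seed=5)
    assert len(surf.years) == 20
    assert surf.deaths.shape == (81, 20, 5)
    # total slice invariant holds per year by construction (checked in init)


def test_parameter_validation():
    with pytest.raises(ValueError):
        toy_rates(ToyParams(causes={"X": CauseParams(hump_height=-1.0)}))
    with pytest.raises(ValueError):
        toy_rates(ToyParams(causes={"X": CauseParams(hump_width=0.0)}))
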