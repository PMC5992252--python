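import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from humpdec import (arriaga, lel_measures, life_expectancy_lost, lifetable)


def test_constant_hazard_closed_form():
    mu = 0.05
    ages = np.arange(10, 111)
    lt = lifetable(np.full(ages.size, mu), ages)
    # discrete closed form: q = mu/(1+mu/2), geometric survival,
    # trapezoidal person-years, exponential tail closure
    p = 1 - mu / (1 + 0.5 * mu)
    lx = p ** np.arange(ages.size)
    Lx = np.empty(ages.size)
    Lx[:-1] = 0.5 * (lx[:-1] + lx[1:])
    Lx[-1] = lx[-1] / mu
    assert np.isclose(lt.ex[0], Lx.sum(), atol=1e-10)
    # and it matches the continuous survival integral 1/mu to 3 decimals
    assert abs(lt.ex[0] - 1.0 / mu) < 1e-3


def test_zero_rates_give_age_span():
    ages = np.arange(10, 91)
    lt = lifetable(np.zeros(ages.size), ages)
    assert np.isclose(lt.ex[0], 80.0)


def test_lifetable_columns_consistent():
    rng = np.random.default_rng(0)
    mx = np.exp(rng.normal(-5, 1, 40))
    lt = lifetable(mx)
    assert np.all(lt.lx[:-1] >= lt.lx[1:])           # survival decreasing
    assert np.allclose(lt.dx[:-1], lt.lx[:-1] - lt.lx[1:])
    assert np.allclose(lt.Tx[:-1] - lt.Tx[1:], lt.Lx[:-1])
    assert np.all((lt.qx >= 0) & (lt.qx <= 1))


def test_negative_rate_rejected():
    with pytest.raises(ValueError, match="negative"):
        lifetable(np.array([0.1, -0.1, 0.2]))


def test_arriaga_conserves_and_antisymmetric():
    rng = np.random.default_rng(42)
    for _ in range(20):
        m1 = np.exp(rng.normal(-6, 1, 81))
        m2 = np.exp(rng.normal(-6, 1, 81))
        lt1, lt2 = lifetable(m1), lifetable(m2)
        c12 = arriaga(lt1, lt2)
        c21 = arriaga(lt2, lt1)
        assert abs(c12.sum() - (lt2.ex[0] - lt1.ex[0])) <= 1e-10
        assert np.max(np.abs(c12 + c21)) < 1e-9


def test_arriaga_localizes_a_single_age_change():
    mx = np.full(60, 0.01)
    mx2 = mx.copy()
    mx2[30] = 0.001
    c = arriaga(lifetable(mx), lifetable(mx2))
    assert np.argmax(np.abs(c)) == 30


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_lower_rates_never_lower_life_expectancy(seed):
    rng = np.random.default_rng(seed)
    mx = np.exp(rng.normal(-5, 1, 50))
    scale = rng.uniform(0.2, 1.0)
    gain = life_expectancy_lost(mx, mx * scale)
    assert gain >= -1e-12


def test_lel_measures_on_toy(toy_fit, toy_dec, toy_noiseless):
    lel = lel_measures(toy_fit, toy_dec, toy_noiseless)
    assert lel.L1 > 0 and lel.L2 > 0 and lel.L3 > 0
    assert lel.L3 <= lel.L2 + 1e-12
    # age split of L1 conserves; cause splits sum to the totals
    assert abs(lel.age_contributions.sum() - lel.L1) < 1e-9
    assert abs(sum(lel.cause_years_L1.values()) - lel.L1) < 1e-9
    assert abs(sum(lel.cause_years_L2.values()) - lel.L2) < 1e-9
    # shares sum to 1 per measure in the exported frame
    frame = lel.to_frame()
    for meas in ("L1", "L2"):
        s = frame[(frame.measure == meas) & (frame.cause != "all")]["share"].sum()
        assert abs(s - 1.0) < 1e-9
    # hump deletion contributions concentrate at young adult ages
    peak_age = lel.ages[np.argmax(lel.age_contributions)]
    assert 13 <= peak_age <= 30


def test_lel_without_decomposition(toy_fit, toy_noiseless):
    lel = lel_measures(toy_fit, None, toy_noiseless)
    assert lel.L1 == 0.0 and lel.L3 == 0.0
    assert lel.L2 > 0


def test_lel_window_validation(toy_fit, toy_dec, toy_noiseless):
    with pytest.raises(ValueError, match="window"):
        lel_measures(toy_fit, toy_dec, toy_noiseless, window=(5, 34))
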