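import numpy as np
import pytest

from humpdec import AbridgedGroups, graduate_counts, rescale_to_total


def _gompertz_setup(noise_seed=None):
    ages = np.arange(10, 90)
    true = 1e-4 * np.exp(0.1 * (ages - 10))
    e = np.full(ages.size, 1e6)
    bounds = [(a, a + 5) for a in range(10, 90, 5)]
    G = np.zeros((len(bounds), ages.size))
    for g, (lo, hi) in enumerate(bounds):
        G[g, (ages >= lo) & (ages < hi)] = 1.0
    y = G @ (e * true)
    if noise_seed is not None:
        y = np.random.default_rng(noise_seed).poisson(y).astype(float)
    return ages, true, e, bounds, G, y


def test_gompertz_recovery_within_2pct():
    ages, true, e, bounds, G, y = _gompertz_setup(noise_seed=3)
    gr = AbridgedGroups(bounds=bounds, counts={"X": y},
                        single_age_exposures=e)
    rates = graduate_counts(gr)["X"]
    sel = (ages >= 15) & (ages <= 85)
    assert np.max(np.abs(rates[sel] / true[sel] - 1)) < 0.02


def test_group_totals_preserved():
    ages, true, e, bounds, G, y = _gompertz_setup()
    gr = AbridgedGroups(bounds=bounds, counts={"X": y},
                        single_age_exposures=e)
    rates = graduate_counts(gr)["X"]
    fitted_groups = G @ (e * rates)
    assert np.max(np.abs(fitted_groups / y - 1)) < 1e-4


def test_unit_width_groups_equal_direct_smooth():
    ages, true, e, _, _, _ = _gompertz_setup()
    bounds1 = [(int(a), int(a) + 1) for a in ages]
    gr = AbridgedGroups(bounds=bounds1, counts={"X": e * true},
                        single_age_exposures=e)
    rates = graduate_counts(gr)["X"]
    assert np.max(np.abs(rates / true - 1)) < 1e-3


def test_all_zero_cause_floored_with_warning():
    ages, true, e, bounds, G, y = _gompertz_setup()
    gr = AbridgedGroups(bounds=bounds,
                        counts={"X": y, "Z": np.zeros(len(bounds))},
                        single_age_exposures=e)
    with pytest.warns(UserWarning, match="all counts zero"):
        rates = graduate_counts(gr)
    assert np.all(rates["Z"] == 1e-12)


def test_insufficient_groups():
    e = np.full(80, 1e6)
    gr = AbridgedGroups(bounds=[(10, 90)], counts={"X": np.array([5.0])},
                        single_age_exposures=e)
    with pytest.raises(ValueError, match="insufficient groups"):
        graduate_counts(gr)


def test_scale_invariance():
    ages, true, e, bounds, G, y = _gompertz_setup()
    g1 = graduate_counts(AbridgedGroups(bounds=bounds, counts={"X": y},
                                        single_age_exposures=e))["X"]
    g2 = graduate_counts(AbridgedGroups(bounds=bounds, counts={"X": 7 * y},
                                        single_age_exposures=7 * e))["X"]
    assert np.allclose(g1, g2, rtol=1e-5)


def test_group_tiling_validation():
    e = np.full(10, 1e3)
    with pytest.raises(ValueError, match="gap or overlap"):
        AbridgedGroups(bounds=[(10, 15), (16, 20)],
                       counts={"X": np.array([1.0, 1.0])},
                       single_age_exposures=e)
    with pytest.raises(ValueError, match="negative"):
        AbridgedGroups(bounds=[(10, 15), (15, 20)],
                       counts={"X": np.array([1.0, -1.0])},
                       single_age_exposures=e)


def test_rescale_conservation():
    rng = np.random.default_rng(5)
    total = np.exp(rng.normal(-6, 0.5, 30))
    cause = {c: np.exp(rng.normal(-8, 0.5, 30)) for c in "abc"}
    out = rescale_to_total(cause, total)
    s = np.sum(list(out.values()), axis=0)
    assert np.max(np.abs(s - total)) <= 1e-14


def test_rescale_identity_and_proportionality():
    total = np.array([0.004, 0.004])
    cause = {"a": np.array([0.001, 0.002]), "b": np.array([0.001, 0.002])}
    out = rescale_to_total({"a": total * 0.25, "b": total * 0.75}, total)
    assert np.allclose(out["a"], total * 0.25)
    out2 = rescale_to_total(cause, total)
    assert np.allclose(out2["a"], [0.002, 0.002])


def test_rescale_zero_sum_errors():
    total = np.array([0.001, 0.002])
    cause = {"a": np.array([0.0, 0.001])}
    with pytest.raises(ValueError, match="zero cause-sum"):
        rescale_to_total(cause, total)
    with pytest.raises(ValueError, match="no causes"):
        rescale_to_total({}, total)
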