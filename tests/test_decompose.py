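import numpy as np
import pytest

from humpdec import (DEFAULT_TOY, build_augmented_system,
                     contributions_summary, decompose_causes,
                     single_cause_contribution, toy_components)


def test_augmented_structure(toy_noiseless, toy_fit):
    sys2 = build_augmented_system(toy_noiseless, toy_fit, ["A", "B"])
    m = len(toy_noiseless.ages)
    assert sys2.response.size == 4 * m
    assert sys2.composite.shape == (4 * m, 4 * m)
    # data rows: cause-deleted counts
    dA = toy_noiseless.total_deaths() - toy_noiseless.cause_deaths("A")
    assert np.allclose(sys2.response[:m], dA)
    # hump constraint row: (K-1) * dhat_H
    assert np.allclose(sys2.response[2 * m:3 * m], toy_fit.dhat_H)
    # weights: 1 on data rows, constraint weight on pseudo rows
    assert np.all(sys2.reg_weights[:2 * m] == 1.0)
    assert np.all(sys2.reg_weights[2 * m:] == sys2.constraint_weight)


def test_requires_two_causes(toy_noiseless, toy_fit):
    with pytest.raises(ValueError, match="at least 2"):
        build_augmented_system(toy_noiseless, toy_fit, ["A"])
    with pytest.raises(ValueError, match="not on the surface"):
        build_augmented_system(toy_noiseless, toy_fit, ["A", "zz"])


def test_constraints_conserved(toy_dec, toy_fit):
    assert toy_dec.converged
    assert toy_dec.constraint_residual_H < 1e-3
    assert toy_dec.constraint_residual_S < 1e-3
    e = toy_dec.exposures
    assert np.allclose(e * toy_dec.sum_delta_H, toy_fit.dhat_H,
                       rtol=1e-2, atol=1e-3)


def test_shares_recovered(toy_dec):
    hump, _ = toy_components(DEFAULT_TOY)
    e = toy_dec.exposures
    true_tot = {c: float(np.sum(e * hump[c])) for c in ("A", "B", "C")}
    grand = sum(true_tot.values())
    summ = contributions_summary(toy_dec).set_index("cause")
    for c in ("A", "B", "C"):
        assert abs(summ.loc[c, "share"] - true_tot[c] / grand) < 0.05, c
    # peak ages land near the generating hump locations
    for c, loc in (("A", 21.0), ("B", 24.0), ("C", 18.0)):
        assert abs(summ.loc[c, "peak_age"] - loc) <= 3.0, c


def test_core_region_delta_recovery(toy_dec):
    # single-age allocation is weakly identified; require 20% in the core
    # region where the total hump exceeds 10% of its peak
    hump, _ = toy_components(DEFAULT_TOY)
    total_hump = np.sum([hump[c] for c in ("A", "B", "C")], axis=0)
    core = total_hump > 0.1 * total_hump.max()
    est = toy_dec.sum_delta_H
    assert np.max(np.abs(est[core] / total_hump[core] - 1)) < 0.2


def test_inert_cause_gets_tiny_share(toy_noiseless, toy_fit):
    # wrongly including the pure-Gompertz cause D: its share stays < 5%
    dec = decompose_causes(toy_noiseless, toy_fit, ["A", "B", "C", "D"])
    summ = contributions_summary(dec).set_index("cause")
    assert abs(summ.loc["D", "share"]) < 0.05


def test_single_cause_contribution(toy_noiseless, toy_fit):
    hump, _ = toy_components(DEFAULT_TOY)
    dH, dS = single_cause_contribution(toy_noiseless, toy_fit, "C")
    # deleting C removes roughly C's hump deaths from the hump component
    e = toy_noiseless.exposure()
    est = float(np.sum(e * dH))
    true = float(np.sum(e * hump["C"]))
    assert abs(est / true - 1) < 0.35


def test_grid_mismatch_rejected(toy_noiseless, toy_fit):
    import dataclasses

    bad_fit = dataclasses.replace(toy_fit, ages=toy_fit.ages[:-1])
    with pytest.raises(ValueError, match="age grids"):
        build_augmented_system(toy_noiseless, bad_fit, ["A", "B"])
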