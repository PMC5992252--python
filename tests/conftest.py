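import numpy as np
import pytest

from humpdec import (DEFAULT_TOY, decompose_causes, fit_sse, sample_deaths,
                     toy_rates)


@pytest.fixture(scope="session")
def toy_noiseless():
    """Single-year noiseless surface from the default toy landscape."""
    return sample_deaths(toy_rates(DEFAULT_TOY), DEFAULT_TOY.exposure,
                         noiseless=True)


@pytest.fixture(scope="session")
def toy_fit(toy_noiseless):
    surf = toy_noiseless
    return fit_sse(surf.total_deaths(), surf.exposure(),
                   ages=surf.ages.astype(float))


@pytest.fixture(scope="session")
def toy_dec(toy_noiseless, toy_fit):
    return decompose_causes(toy_noiseless, toy_fit, ["A", "B", "C"])


@pytest.fixture(scope="session")
def true_components():
    """True per-cause hump and background schedules of the default toy."""
    from humpdec import toy_components

    hump, background = toy_components(DEFAULT_TOY)
    return hump, background


@pytest.fixture(scope="session")
def ages():
    return np.asarray(DEFAULT_TOY.ages, dtype=float)
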