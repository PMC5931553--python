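import dataclasses

import pytest

from arclake.synthetic import (
    ClimateScenario,
    SedimentScenario,
    gen_core,
    gen_daily_climate,
)

CONSTANT_RATE = SedimentScenario(epochs=((1900.0, 2015.0, 0.015),), noise_cv=0.0)
TWO_EPOCH = SedimentScenario(
    epochs=((1900.0, 1970.0, 0.008), (1970.0, 2015.0, 0.02)), noise_cv=0.0
)


@pytest.fixture(scope="session")
def constant_rate_core():
    """Zero-noise constant-rate core: CRS should be exact."""
    return gen_core(CONSTANT_RATE)


@pytest.fixture(scope="session")
def two_epoch_core():
    """Zero-noise core with one rate change (closed-form age-depth map)."""
    return gen_core(TWO_EPOCH)


@pytest.fixture(scope="session")
def default_core():
    """Zero-noise paper-mimicking core (multi-epoch, accelerating rates)."""
    return gen_core(dataclasses.replace(SedimentScenario(), noise_cv=0.0))


@pytest.fixture(scope="session")
def clean_climate():
    """Noise-free climate scenario: phenology must match analytic truth."""
    sc = ClimateScenario(sic_noise_sd=0.0, noise_sd=0.0, interannual_sd=0.0)
    sic, stations, truth = gen_daily_climate(sc)
    return sc, sic, stations, truth


@pytest.fixture(scope="session")
def noisy_climate():
    """Default noisy climate scenario with retained ground truth."""
    sc = ClimateScenario(seed=11)
    sic, stations, truth = gen_daily_climate(sc)
    return sc, sic, stations, truth
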