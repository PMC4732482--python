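import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from acclim.config import GeneratorConfig

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_small_config(n: int = 5, **updates) -> GeneratorConfig:
    """A 2-population x 2-temperature design for fast unit tests."""
    pops = ["A", "B"]
    temps = [8.0, 19.0]

    def cells(value):
        return {t: {p: value for p in pops} for t in temps}

    base = dict(
        populations=pops,
        acclimation_temps=temps,
        n_per_cell=cells(n),
        mass_mean_by_cell=cells(100.0),
        condition_by_cell=cells(1.2),
        ctm_mean_by_acclimation={8.0: 26.1, 19.0: 28.9},
        rmr_ref={8.0: 5.0, 19.0: 13.0},
        mmr_ref={8.0: 35.0, 19.0: 34.0},
        recovery_log_slope_by_acclimation={8.0: -4.0, 19.0: -2.6},
    )
    base.update(updates)
    return GeneratorConfig(**base).validate()


@pytest.fixture
def small_config() -> GeneratorConfig:
    return make_small_config()


@pytest.fixture
def noiseless_config() -> GeneratorConfig:
    """Small design with every stochastic component switched off."""
    return make_small_config(
        mass_cv=0.0, condition_sd=0.0, ctm_sd=0.0, rmr_cv=0.0, mmr_cv=0.0,
        recovery_noise_cv=0.0, trace_noise_sd=0.0, background_slope=0.0,
        chase_duration_sd_min=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
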