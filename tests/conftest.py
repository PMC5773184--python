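import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_population():
    """A small synthetic population with default (realistic) settings."""
    import phasevar as pv

    cfg = pv.GeneratorConfig(n_animals=8, seed=7)
    recordings, truth = pv.generate_population(cfg)
    return cfg, recordings, truth


@pytest.fixture
def noise_free_config():
    """All variance components zero: every cycle realizes the target phase."""
    import phasevar as pv

    return pv.GeneratorConfig(
        n_animals=2,
        seed=11,
        period_cv=0.0,
        var_population=0.0,
        var_bilateral=0.0,
        var_repetition=0.0,
        var_cycle=0.0,
    )
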