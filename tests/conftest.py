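import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_config():
    """Small study design used wherever full scale is unnecessary."""
    from padrom.synth import GeneratorConfig

    return GeneratorConfig(n_participants=3, repetitions=2, n_left_handed=2, seed=42)


@pytest.fixture
def noiseless_config():
    """Deterministic generator: no orientation, participant or trial noise."""
    from padrom.synth import GeneratorConfig

    return GeneratorConfig(
        n_participants=2,
        repetitions=1,
        n_left_handed=1,
        orientation_noise_sd=0.0,
        participant_rom_sd=0.0,
        trial_rom_sd=0.0,
        seed=7,
    )
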