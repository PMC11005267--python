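import numpy as np
import pytest

from ecgforecast import NoiseSpec, SynthConfig, add_noise, generate_clean_ecg

# Canonical seeded noisy fixture: drift + mains + broadband, amplitudes
# picked so a meaningful share of the noise energy sits in the detail bands.
CANONICAL_NOISE = (
    NoiseSpec("baseline_drift", 0.1),
    NoiseSpec("powerline", 0.1, 50.0),
    NoiseSpec("white", 0.15),
)
CANONICAL_SEED = 7


@pytest.fixture(scope="session")
def clean_config() -> SynthConfig:
    return SynthConfig(noise_spec=CANONICAL_NOISE, seed=CANONICAL_SEED)


@pytest.fixture(scope="session")
def clean_record(clean_config):
    return generate_clean_ecg(clean_config)


@pytest.fixture(scope="session")
def noisy_pair(clean_config, clean_record):
    noisy = add_noise(clean_record, clean_config.noise_spec, clean_config.seed)
    return clean_record, noisy


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
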