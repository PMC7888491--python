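import pytest

from swinecal import NoiseConfig, generate_experiment, reference_study_config


@pytest.fixture(scope="session")
def zero_noise_experiment():
    """Reference-preset experiment with all measurement noise off."""
    return generate_experiment(reference_study_config(noise=NoiseConfig.zero()), seed=20240)


@pytest.fixture(scope="session")
def noisy_experiment():
    """Reference-preset experiment with default (calibrated) noise."""
    return generate_experiment(reference_study_config(), seed=20241)
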