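import numpy as np
import pytest

from sleepwave import MorseWell, SleepModelParams, synthetic


@pytest.fixture
def well2() -> MorseWell:
    return MorseWell(2.0)


@pytest.fixture
def well20() -> MorseWell:
    return MorseWell(20.0)


@pytest.fixture
def params() -> SleepModelParams:
    """Canonical regular-sleep parameters (sigma=10, j_in=16, bell at cycle 3)."""
    return synthetic.default_params()


@pytest.fixture
def noise_free_config() -> synthetic.GeneratorConfig:
    return synthetic.default_config(seed=0).replace(
        cv_duration=0.0, cv_sws=0.0, first_frac_sd=0.0, poisson_em=False,
        n_nights=4,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230)
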