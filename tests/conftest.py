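import numpy as np
import pytest

from transientad import (ADParams, DimlessParams, NoiseModel, SmapConfig,
                         monitoring_forecasts, random_init,
                         simulate_stochastic, subsample)


@pytest.fixture(scope="session")
def ad_params():
    return ADParams.default()


@pytest.fixture(scope="session")
def dimless_params():
    return DimlessParams.default(alpha=6.0)


@pytest.fixture(scope="session")
def s1_star(ad_params):
    from transientad import dimensional_equilibrium

    return float(dimensional_equilibrium(ad_params)[0][0])


@pytest.fixture(scope="session")
def noisy_series(ad_params):
    """One seeded stochastic realization subsampled to the working grid."""
    rng = np.random.default_rng(np.random.SeedSequence(2024))
    init = random_init(rng)
    full = simulate_stochastic(ad_params, NoiseModel(sigma=0.1), init,
                               t_max=60.0, seed=rng)
    return subsample(full, 0.1)


@pytest.fixture(scope="session")
def noisy_forecasts(noisy_series):
    return monitoring_forecasts(noisy_series, SmapConfig(theta=5.0, h=20))
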