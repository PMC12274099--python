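import numpy as np
import pytest

from smoothlik import SurvivalData


def make_cox_data(seed, n=60, beta=(0.7, -0.4), censor_scale=2.0):
    """Random censored Cox sample with continuous (tie-free) times."""
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    x = rng.standard_normal((n, beta.size))
    latent = rng.exponential(1.0 / np.exp(x @ beta))
    censor = rng.uniform(0.0, censor_scale, n)
    return SurvivalData(np.minimum(latent, censor),
                        (latent <= censor).astype(int), x)


@pytest.fixture
def cox_data():
    return make_cox_data(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
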