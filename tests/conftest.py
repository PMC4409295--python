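import numpy as np
import pytest

import semiaft as sa


@pytest.fixture(scope="session")
def frailty_ds():
    """Moderate gamma-frailty dataset (independent errors), latents retained."""
    return sa.simulate_gamma_frailty(120, 0.0, seed=101)


@pytest.fixture(scope="session")
def frailty_ds_dep():
    """Gamma-frailty dataset with shared-frailty dependence."""
    return sa.simulate_gamma_frailty(120, 1.0, seed=202)


@pytest.fixture(scope="session")
def small_fit(frailty_ds):
    return sa.fit(frailty_ds)


@pytest.fixture(scope="session")
def small_draws(frailty_ds, small_fit):
    return sa.resample(frailty_ds, small_fit, M=120, seed=7)


def toy_dataset(y_x, y_d, delta, Delta, Z):
    return sa.SemicompetingDataset(y_x=np.asarray(y_x, float), y_d=np.asarray(y_d, float),
                                   delta=np.asarray(delta, float),
                                   Delta=np.asarray(Delta, float), Z=np.asarray(Z, float))


def random_alpha(rng, k, scale=1.0):
    return sa.ParamAlpha(rng.normal(0, scale, k), rng.normal(0, scale, k))
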