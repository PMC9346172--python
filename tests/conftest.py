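import numpy as np
import pytest

from toporad.phantoms import PhantomSpec, generate_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_cavity_phantom():
    """Two-cavity phantom with no noise: topology known by construction."""
    spec = PhantomSpec(
        grid_shape=(48, 48, 48),
        n_cavities=2,
        cavity_radius_mm=2.5,
        rim_width_mm=2.0,
        noise_sd_hu=0.0,
        seed=7,
    )
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def small_cohort_tables():
    """A tiny feature table + survival outcome reused across signature tests."""
    rng = np.random.default_rng(99)
    import pandas as pd

    n, p = 80, 12
    X = pd.DataFrame(
        rng.normal(size=(n, p)),
        columns=[f"f{i}" for i in range(p)],
        index=[f"p{i:03d}" for i in range(n)],
    )
    beta = np.zeros(p)
    beta[0] = 1.0
    u = rng.uniform(size=n)
    t = 50 * -np.log(u) / np.exp(X.to_numpy() @ beta)
    censor = 80.0
    events = (t < censor).astype(int)
    times = np.minimum(t, censor)
    return X, times, events
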