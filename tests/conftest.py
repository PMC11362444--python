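import numpy as np
import pandas as pd
import pytest

from surveycog.complexity import load_lexicons
from surveycog.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def lexicons():
    return load_lexicons()


@pytest.fixture(scope="session")
def small_study():
    """Small clean panel (no missingness) shared across tests."""
    return simulate_study(SimulationConfig(n_persons=300, rng_seed=42))


@pytest.fixture(scope="session")
def tiny_scale_sizes():
    return (5, 5, 4, 3, 4, 4, 5, 5)  # 35 items across 8 scales


def simulate_mixed_long(n_persons=400, n_items=50, g11=-0.0003, g01=-0.002,
                        g00=0.42, g10=0.016, tau=None, sigma=0.17, seed=0,
                        center_ability=False):
    """Direct draw from the cross-level interaction model (reduced form):
    the independent data-generating oracle for the mixed-model tests."""
    rng = np.random.default_rng(seed)
    c = rng.integers(0, 10, n_items).astype(float)
    a = rng.normal(15, 4, n_persons)
    if center_ability:
        a -= a.mean()
    if tau is None:
        tau = np.array([[0.004, -0.0004], [-0.0004, 0.0001]])
    u = rng.multivariate_normal([0, 0], tau, n_persons)
    b0 = g00 + g01 * a + u[:, 0]
    b1 = g10 + g11 * a + u[:, 1]
    Y = b0[:, None] + b1[:, None] * c[None, :] + rng.normal(0, sigma, (n_persons, n_items))
    return pd.DataFrame({
        "person_id": np.repeat(np.arange(n_persons), n_items),
        "item_id": np.tile(np.arange(n_items), n_persons),
        "error": Y.ravel(),
        "complexity": np.tile(c, n_persons),
        "ability": np.repeat(a, n_items),
    })
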