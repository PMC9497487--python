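import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pliv

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario1_fit_data():
    """One seeded scenario-1 draw (n=500, rho=0.5) with its generating truth."""
    cfg = pliv.ScenarioConfig(scenario_id=1, n=500, rho=0.5, seed=42)
    data, truth = pliv.generate_scenario(cfg)
    return data, truth


@pytest.fixture(scope="session")
def linear_iv_data():
    """Correlated-error linear IV data: x = 3z + v, y = 2x + u, n = 2000."""
    rng = np.random.default_rng(123)
    n = 2000
    z = rng.standard_normal(n)
    e1, e2 = rng.standard_normal(n), rng.standard_normal(n)
    v = 0.5 * e1
    u = 0.5 * (0.6 * e1 + 0.8 * e2)
    x = 3.0 * z + v
    y = 2.0 * x + u
    return pliv.Dataset(y=y, x=x, z=z)
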