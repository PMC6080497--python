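import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import canemetrics as cm
from canemetrics.uncertainty import build_precision_table

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_campaign():
    """One realization of the default synthetic campaign."""
    cfg = cm.default_truth_config(seed=1)
    return cfg, cm.simulate_campaign(cfg)


@pytest.fixture(scope="session")
def default_fits(default_campaign):
    _, camp = default_campaign
    return cm.fit_campaign(camp)


@pytest.fixture(scope="session")
def default_precision(default_campaign, default_fits):
    _, camp = default_campaign
    return build_precision_table(camp, default_fits)


@pytest.fixture(scope="session")
def clean_logistic_data():
    """Noise-free logistic samples (delta_y=2.5, k=0.03, t0=150)."""
    t = np.array([20.0, 60.0, 100.0, 140.0, 180.0, 220.0, 280.0, 360.0])
    y = 2.5 / (1.0 + np.exp(-0.03 * (t - 150.0)))
    return t, y
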