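import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ratiomics as rm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_panel():
    """10-metabolite panel containing the default planted pair."""
    return rm.make_panel(10)


@pytest.fixture(scope="session")
def effects():
    return rm.EffectSpec()


@pytest.fixture(scope="session")
def null_effects():
    """No planted ratio signal anywhere (covariate effects retained)."""
    return rm.EffectSpec(
        clamp_effects={},
        ogtt_effect=0.0,
        logistic_beta=0.0,
        log_hr=0.0,
    )


@pytest.fixture(scope="session")
def clamp_bundle(small_panel, effects):
    return rm.simulate_clamp_cohort(small_panel, effects, n_families=54, seed=42)


@pytest.fixture()
def positive_matrix():
    rng = np.random.default_rng(3)
    vals = np.exp(rng.normal(0, 0.5, size=(40, 6)))
    return pd.DataFrame(vals, columns=[f"M{i}" for i in range(6)])
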