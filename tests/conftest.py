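import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from integrinscore.simulate import SimConfig, simulate_cohort

settings.register_profile(
    "fast",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


@pytest.fixture(scope="session")
def null_cohort():
    """One-cancer cohort with no planted survival effects (n=200)."""
    cfg = SimConfig(
        n_cancers=1, samples_per_cancer=200, frac_oncogenic=0.0, frac_protective=0.0, seed=77
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_matrix():
    return pd.DataFrame(
        [[0.0, 1.0, 2.0], [3.0, 4.0, 5.0]],
        index=["ITGA2", "ITGB1"],
        columns=["S1", "S2", "S3"],
    )
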