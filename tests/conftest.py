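import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vset_interact as vi

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_pair():
    """A compact paired cohort with two planted interactions."""
    cfg = vi.default_config(
        seed=42,
        n_individuals_per_cohort=(300, 200),
        n_genes=12,
        interaction_pairs=[(0, 1, 0.8), (2, 3, 0.8)],
    )
    return vi.simulate_cohort_pair(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
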