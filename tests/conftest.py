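import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import macpolar as mp

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: a-priori master seed for every multi-seed experiment in the suite
MASTER_SEED = 20260924


def derive_seeds(master: int, k: int) -> list[int]:
    """Deterministic child seeds below 2**31 from one master seed."""
    state = np.random.SeedSequence(master).generate_state(k, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


@pytest.fixture(scope="session")
def clusters():
    return mp.default_clusters()


@pytest.fixture(scope="session")
def cohort():
    """One seeded cohort with the default study conditions (δ = 2·noise_sd)."""
    cfg = mp.SyntheticConfig(seed=derive_seeds(MASTER_SEED, 1)[0])
    return mp.simulate_cohort(cfg)


@pytest.fixture()
def toy_matrix():
    """6-gene, 4-sample matrix with hand-set two-level rows.

    Every row is a permutation of [0,0,1,1], so each gene's step fit is
    exact: threshold 0.5, population SD 0.5, normalized value (v − 1)/1.5.
    """
    data = {
        "C13_001": [0, 0, 1, 1],
        "C13_002": [0, 1, 0, 1],
        "C14_001": [1, 0, 0, 1],
        "C14_002": [1, 1, 0, 0],
        "C3_001": [0, 1, 1, 0],
        "C3_002": [1, 0, 1, 0],
    }
    return pd.DataFrame(data, index=["s1", "s2", "s3", "s4"]).T.astype(float)
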