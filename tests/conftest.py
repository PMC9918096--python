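import numpy as np
import pandas as pd
import pytest

from mirseed import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort reused by read-only tests."""
    cfg = SimConfig(n_naive=4, n_sham=6, n_tbi=20, n_mirna=80,
                    n_injury_responsive=8, t2_grid=(8, 8, 4), seed=11)
    return simulate_cohort(cfg)


@pytest.fixture
def random_counts(rng):
    """Random sparse-ish count matrix for oracle comparisons."""
    m, n = 40, 12
    mu = rng.lognormal(2.5, 1.5, size=(m, 1))
    counts = rng.poisson(mu * rng.uniform(0.5, 2.0, size=(m, n)))
    return pd.DataFrame(counts, index=[f"miR-{i}" for i in range(m)],
                        columns=[f"s{j}" for j in range(n)])
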