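import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from evmir import SimConfig, normalize, simulate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated training-size cohort (30 PDAC / 18 CP) with planted markers."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_norm(default_cohort):
    return normalize.normalize_counts(default_cohort.counts)


@pytest.fixture()
def toy_counts():
    """Tiny hand-checkable count matrix (3 miRNAs x 2 specimens)."""
    return pd.DataFrame(
        {"S1": [1, 0, 3], "S2": [2, 5, 1]},
        index=pd.Index(["A", "B", "C"], name="mirna_id"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
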