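import numpy as np
import pandas as pd
import pytest

from methylarow import BetaMatrix, SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 3,000-probe, 104-sample synthetic cohort with ground truth."""
    config = SimulationConfig(n_probes=3000, n_maf_fail=30, n_detp_fail=20, seed=7)
    return generate_cohort(config, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_beta(rng):
    """A 20x6 beta matrix with a few missing values."""
    vals = rng.random((20, 6))
    vals[2, 3] = np.nan
    vals[7, 0] = np.nan
    probes = [f"cg{i:08d}" for i in range(1, 21)]
    samples = [f"S{j}" for j in range(6)]
    return BetaMatrix(pd.DataFrame(vals, index=probes, columns=samples))
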