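import warnings

import numpy as np
import pandas as pd
import pytest

from locusnet.simulate import SimulationConfig, simulate_cohort

warnings.filterwarnings("ignore", message="no candidate power")


@pytest.fixture(scope="session")
def small_sim():
    """Small planted cohort shared by fast unit tests: 500 genes, three
    modules (120/90/60), 60 reference and 30 test samples."""
    cfg = SimulationConfig(
        n_genes=500,
        module_sizes=[120, 90, 60],
        n_samples_ref=60,
        n_samples_test=30,
        n_interval_genes=7,
        seed=42,
    )
    return (cfg, *simulate_cohort(cfg))


@pytest.fixture(scope="session")
def default_sim():
    """The default desk-scale cohort (2,000 genes, five modules, n_ref=100)."""
    cfg = SimulationConfig(seed=1)
    return (cfg, *simulate_cohort(cfg))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_expression(n_genes: int, n_samples: int, seed: int = 0) -> pd.DataFrame:
    r = np.random.default_rng(seed)
    return pd.DataFrame(
        r.standard_normal((n_genes, n_samples)) + r.normal(7, 2, (n_genes, 1)),
        index=[f"N{i:04d}" for i in range(n_genes)],
        columns=[f"S{j:03d}" for j in range(n_samples)],
    )
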