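import numpy as np
import pytest

from drivermaps import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated cohort shared by tests that only need plausible
    data (not statistical power): 80 genes, 6 TSGs + 6 OGs."""
    cfg = SimConfig(n_genes=80, n_samples=400, mean_gene_len=300,
                    n_tsg=6, n_og=6, mut_rate_per_mb_per_sample=20.0, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
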