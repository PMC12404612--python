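import numpy as np
import pandas as pd
import pytest

from wormexpress import SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """60 worms x 150 genes with default-style structure (session-cached)."""
    spec = SimulationSpec(n_worms=60, n_replicates=3, n_genes=150, seed=7)
    pheno, expr, truth = simulate_dataset(spec)
    return spec, pheno, expr, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_grouped_data(seed, n=120, q=4, beta=(1.0, 2.0), sigma_u=1.0,
                      sigma_e=1.0):
    """Simple mixed-model dataset with known parameters."""
    r = np.random.default_rng(seed)
    groups = np.repeat(np.arange(q), n // q)
    u = r.normal(0, sigma_u, q)[groups]
    x = r.normal(size=n)
    y = beta[0] + beta[1] * x + u + r.normal(0, sigma_e, n)
    return x, y, groups
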