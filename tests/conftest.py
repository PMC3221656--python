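import numpy as np
import pytest

import hbcount as hb


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    return hb.CountTable(
        counts=np.array([[5, 2, 9], [1, 7, 4], [8, 8, 2], [3, 1, 6]]),
        population_label="toy",
    )


@pytest.fixture(scope="session")
def null_table():
    """One dataset from the standard null design (20 replicates, 3 choices)."""
    gen = np.random.default_rng(2024)
    table, _, _ = hb.generate_dataset(hb.SimulationConfig(n_datasets=1, seed=2024), gen)
    return table


@pytest.fixture(scope="session")
def fitted_chain(null_table):
    """A moderately long chain on the null table, shared across tests."""
    cfg = hb.MCMCConfig(n_steps=4000, burnin=1000, seed=99)
    return hb.run_chain(null_table, config=cfg)
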