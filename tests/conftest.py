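import numpy as np
import pandas as pd
import pytest

from lncwgcna.simulate import (
    ProbeUniverseConfig,
    SimulationConfig,
    simulate_expression,
    simulate_probe_universe,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One draw of the default stated world (22 samples, 3 modules, 3 hubs)."""
    return simulate_expression(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_universe():
    """Default probe/transcript universe with planted decoys."""
    return simulate_probe_universe(ProbeUniverseConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def small_matrix(rng):
    """Random 30-gene x 12-sample expression frame."""
    x = rng.standard_normal((30, 12))
    return pd.DataFrame(
        x,
        index=[f"g{i}" for i in range(30)],
        columns=[f"s{j}" for j in range(12)],
    )
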