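import numpy as np
import pandas as pd
import pytest

from lateralyzer import SampleSheet, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_individuals=6, n_genes=400, seed=7, asynchrony_delta=0.25,
        n_sets=20, set_size_range=(10, 40),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture
def paired_sheet():
    """Hand-built 4-pair sample sheet."""
    rows = []
    for i, (age, sex) in enumerate([(8.0, "M"), (9.0, "F"), (10.0, "M"), (12.0, "F")]):
        for side in ("L", "R"):
            rows.append(
                {
                    "sample_id": f"E{i}_{side}",
                    "individual": f"E{i}",
                    "side": side,
                    "structure": "s1",
                    "age_pcw": age,
                    "sex": sex,
                }
            )
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
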