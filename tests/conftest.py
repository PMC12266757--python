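import numpy as np
import pytest

from rnage import (
    DatasetPanelConfig,
    SimulationConfig,
    derive_signatures,
    simulate_training_tables,
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions: 800 genes, 40 planted per class."""
    return SimulationConfig(
        n_genes=800,
        planted_per_class={c: 40 for c in ("Pan", "pF", "Neuronal", "FC", "SN")},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_panel():
    return DatasetPanelConfig(top_n=40)


@pytest.fixture(scope="session")
def small_training(small_config, small_panel):
    return simulate_training_tables(small_config, small_panel)


@pytest.fixture(scope="session")
def small_signatures(small_training, small_panel):
    tables, _ = small_training
    signatures, _ = derive_signatures(tables, small_panel)
    return signatures


@pytest.fixture(scope="session")
def small_truth(small_training):
    return small_training[1]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
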