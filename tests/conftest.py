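import numpy as np
import pandas as pd
import pytest

from lipidsig import AnalysisConfig, PlantedEffect, SimulationConfig, generate_panel


@pytest.fixture(scope="session")
def small_config():
    """A small, fully observable panel configuration for fast unit tests."""
    return SimulationConfig(
        n_per_group=12,
        n_metabolites=30,
        n_plates=2,
        zero_missing_rate=0.05,
        is_missing_rate=0.03,
        poorly_detected_fraction=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_panel(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """No missingness at all: every cell observed."""
    return SimulationConfig(
        n_per_group=12,
        n_metabolites=20,
        n_plates=2,
        zero_missing_rate=0.0,
        is_missing_rate=0.0,
        poorly_detected_fraction=0.0,
        loq_quantile=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_panel(clean_config):
    return generate_panel(clean_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def three_group_values():
    """Printed 3x5 fixture used by the rank-test oracles."""
    values = np.array(
        [4.2, 5.1, 3.9, 4.8, 5.5,
         6.1, 5.9, 7.2, 6.5, 5.8,
         8.1, 7.9, 6.9, 9.0, 8.4]
    )
    groups = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5, dtype=object)
    return pd.DataFrame({"m1": values}), groups
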