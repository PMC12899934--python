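import numpy as np
import pytest

from dietsim import (default_food_table, default_pattern_specs,
                     default_requirements, simulate_population)


@pytest.fixture(scope="session")
def db():
    return default_food_table()


@pytest.fixture(scope="session")
def requirements():
    return default_requirements()


@pytest.fixture(scope="session")
def specs():
    return default_pattern_specs()


@pytest.fixture(scope="session")
def default_pop(db):
    """Full-size default simulation (375 per pattern, seed 42)."""
    return simulate_population(db, n_per_pattern=375, seed=42)


@pytest.fixture(scope="session")
def small_pop(db):
    """Small population for fast structural tests."""
    return simulate_population(db, n_per_pattern=40, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2025)
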