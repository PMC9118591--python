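import numpy as np
import pandas as pd
import pytest

from movecoda.simulate import SimulationConfig, simulate_cohort


def random_compositions(rng: np.random.Generator, n: int, D: int = 4,
                        total: float = 1.0) -> np.ndarray:
    """Strictly positive random compositions with a wide log-scale spread."""
    logs = rng.uniform(-3.0, 3.0, size=(n, D))
    x = np.exp(logs)
    return x * (total / x.sum(axis=1, keepdims=True))


@pytest.fixture(scope="session")
def sim_cohort():
    """A moderate synthetic cohort shared across model tests."""
    return simulate_cohort(SimulationConfig(n_subjects=400, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
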