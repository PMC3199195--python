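import numpy as np
import pytest

from repsync import (
    CouplingParams,
    RepressilatorParams,
    find_limit_cycle,
)


@pytest.fixture(scope="session")
def default_params() -> RepressilatorParams:
    return RepressilatorParams()


@pytest.fixture(scope="session")
def limit_cycle(default_params):
    """Converged limit cycle of the default cell (shared across tests)."""
    return find_limit_cycle(default_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20111020)


def random_states(rng: np.random.Generator, n: int, size: int = 12) -> np.ndarray:
    """Random nonnegative states spanning the concentration scales of the orbit."""
    scales = np.array([50.0, 200.0, 80.0, 3.0, 3.0, 1.0] * (size // 6))
    return rng.random((n, size)) * scales


@pytest.fixture()
def coupling() -> CouplingParams:
    return CouplingParams(0.04)
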