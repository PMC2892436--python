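import numpy as np
import pytest

from sigmofit import Dataset, SimulationConfig, make_true_curve

TRUE_B, TRUE_D, TRUE_E = -9.90, 11.07, 24.75


@pytest.fixture(scope="session")
def x_grid() -> np.ndarray:
    return np.arange(10, 36, dtype=float)


@pytest.fixture(scope="session")
def true_curve() -> Dataset:
    return make_true_curve(SimulationConfig())


@pytest.fixture
def make_noisy(true_curve):
    """Factory for reproducible noisy replicates of the true curve."""

    def _make(sd: float = 0.02, seed: int = 0) -> Dataset:
        rng = np.random.default_rng(seed)
        return Dataset(true_curve.x,
                       true_curve.y + rng.normal(0.0, sd, true_curve.n),
                       true_sd=sd)

    return _make
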