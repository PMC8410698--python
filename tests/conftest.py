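import numpy as np
import pytest

import ramanfda as rf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cubic_basis():
    """Clamped cubic basis with 20 functions on [0, 1]."""
    return rf.build_basis((0.0, 1.0), 20, 4)


@pytest.fixture
def smooth_spectra(rng):
    """30 smooth low-frequency curves on a 200-point grid (plus mild noise)."""
    grid = np.linspace(0.0, 1.0, 200)
    n = 30
    coef = rng.normal(size=(n, 4))
    X = (
        coef[:, [0]]
        + coef[:, [1]] * np.sin(2 * np.pi * grid)
        + coef[:, [2]] * np.cos(4 * np.pi * grid)
        + coef[:, [3]] * grid**2
    )
    X += rng.normal(0.0, 0.05, size=X.shape)
    labels = np.array(["a", "b"] * (n // 2))
    return rf.SpectraMatrix(X, grid, labels)


@pytest.fixture
def easy_dataset():
    """A clearly separable simulated cell (large shift, high SNR)."""
    return rf.simulate_dataset(rf.SimulationConfig(shift=0.05, snr=100, seed=11))


@pytest.fixture
def small_dataset():
    """A reduced-size simulated cell for fast CV tests."""
    return rf.simulate_dataset(
        rf.SimulationConfig(n_per_class=30, n_points=256, shift=0.05, snr=10, seed=5)
    )
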