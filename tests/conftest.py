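import warnings

import numpy as np
import pytest

from lassokalman import (
    Epoch,
    EpochObservations,
    ExpressionSeries,
    SimConfig,
    simulate,
)

# near-saturated LASSO fits legitimately hit the iteration cap while
# scanning the regularization grid
warnings.filterwarnings("ignore", message="Objective did not converge")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_series(rng):
    """4 genes x 8 samples with numeric time labels."""
    values = rng.standard_normal((4, 8))
    return ExpressionSeries(values=values, time_labels=list(range(8)))


def make_observations(rng, p=4, n_epochs=3, m=5, A=None, noise_sd=0.0):
    """Observations from a fixed (static) network A: Y(k) = A X(k) + noise."""
    if A is None:
        A = rng.standard_normal((p, p)) * (rng.random((p, p)) < 0.4)
        np.fill_diagonal(A, -rng.uniform(0.2, 1.0, p))
    epochs = []
    for _ in range(n_epochs):
        X = rng.standard_normal((p, m))
        Y = A @ X + noise_sd * rng.standard_normal((p, m))
        epochs.append(Epoch(X=X, Y=Y))
    return A, EpochObservations(epochs=epochs)


@pytest.fixture
def bench_instance():
    """One ten-gene / five-epoch / seven-observation benchmark instance."""
    cfg = SimConfig(seed=42)
    networks, obs = simulate(cfg)
    return cfg, networks, obs
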