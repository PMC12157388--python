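import numpy as np
import pytest

from kompot import make_mixture_manifold, plant_expression


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def gaussian_2d():
    """2000 samples from a standard 2-D Gaussian with analytic log-density."""
    rng = np.random.default_rng(42)
    X = rng.standard_normal((2000, 2))
    true_logpdf = -0.5 * np.sum(X**2, axis=1) - np.log(2 * np.pi)
    return X, true_logpdf


@pytest.fixture(scope="session")
def planted_dataset():
    """Two-component manifold, 600 cells/condition, planted DE effects."""
    ds = make_mixture_manifold(n_per_condition=(600, 600), seed=7)
    return plant_expression(
        ds,
        n_genes=50,
        effect_spec=[
            {"type": "global_shift", "delta": 1.0, "n": 5},
            {"type": "opposing_shift", "delta": 1.0, "n": 5},
        ],
        noise_sd=0.2,
        seed=8,
    )
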