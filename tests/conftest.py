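import logging

import numpy as np
import pytest

from kanloc.splines import EdgeActivationParams, GridSpec, uniform_grid


@pytest.fixture(autouse=True)
def _quiet_grid_warnings(caplog):
    # grid-update skips on dead hidden nodes are expected during training
    logging.getLogger("kanloc.network").setLevel(logging.ERROR)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def grid53():
    """Uniform grid, G=5, kappa=3, over [-1, 1]."""
    return uniform_grid(5, 3, -1.0, 1.0)


@pytest.fixture
def edge_params(grid53, rng):
    return EdgeActivationParams(
        w_b=0.7, w_s=1.3,
        coeffs=rng.normal(0, 1, grid53.n_bases),
        grid=grid53,
    )


def random_gridspec(rng, G=None, kappa=None):
    """Random non-degenerate knot configuration."""
    G = G or int(rng.integers(3, 9))
    kappa = kappa or int(rng.integers(1, 4))
    # strictly increasing interior, uniform-ish extension
    steps = rng.uniform(0.2, 1.5, G)
    interior = np.concatenate([[rng.uniform(-2, 0)], ]) + np.concatenate(
        [[0.0], np.cumsum(steps)]
    )
    h = (interior[-1] - interior[0]) / G
    knots = np.concatenate([
        interior[0] - h * np.arange(kappa, 0, -1),
        interior,
        interior[-1] + h * np.arange(1, kappa + 1),
    ])
    return GridSpec(knots=knots, G=G, kappa=kappa, epsilon=0.5,
                    domain_lo=float(interior[0]), domain_hi=float(interior[-1]))
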