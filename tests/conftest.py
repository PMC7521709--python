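import numpy as np
import pytest

import homeomix as hx


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_system(rng):
    """Stable 4-feature, 3-chemical, 1-disease system with mild coupling."""
    c, n_N, n_D = 4, 3, 1
    eps = 0.1 * rng.standard_normal((c, c))
    np.fill_diagonal(eps, 1.0)
    return hx.FeatureSystem(
        h0=rng.uniform(1, 10, c),
        eps=eps,
        k=rng.uniform(0.5, 2.0, c),
        nu=rng.standard_normal((c, n_N)),
        delta=rng.standard_normal((c, n_D)),
        n_ref=rng.uniform(0.5, 1.5, n_N),
    )


@pytest.fixture
def small_comp(small_system):
    return hx.compound_potencies(small_system)
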