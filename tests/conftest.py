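import numpy as np
import pytest

from frusta.body import StationSeries
from frusta.synthetic import SyntheticBodyParams, make_theropod_body, simulate_tree


@pytest.fixture(scope="session")
def default_body_leg():
    """One deterministic parametric body + leg shared across tests."""
    return make_theropod_body(SyntheticBodyParams(seed=0))


@pytest.fixture(scope="session")
def yule_tree_20():
    return simulate_tree(20, seed=11)


@pytest.fixture(scope="session")
def yule_tree_50():
    return simulate_tree(50, seed=7)


def cylinder_series(r_dv=1.0, r_lm=0.5, length=4.0, n=3, region="trunk"):
    """Tiny constant-section station series (n stations)."""
    x = np.linspace(0.0, length, n)
    return StationSeries(
        x=x,
        y_dorsal=np.full(n, r_dv),
        y_ventral=np.full(n, -r_dv),
        z_half=np.full(n, r_lm),
        region=np.array([region] * n, dtype=object),
    )
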