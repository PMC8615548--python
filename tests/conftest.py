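import warnings

import numpy as np
import pytest

from knotscope import ClosureParams, synthetic_data as sd


@pytest.fixture(autouse=True)
def _quiet_collinear_warning():
    # pure-tail subchains fall back to direct closure by design
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="collinear chain")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def trefoil_curve():
    return sd.torus_knot(2, 3, 120)


@pytest.fixture(scope="session")
def fig8_curve():
    return sd.figure_eight(160)


@pytest.fixture(scope="session")
def cinq_curve():
    return sd.torus_knot(2, 5, 200)


@pytest.fixture(scope="session")
def circle_curve():
    return sd.circle(40)


@pytest.fixture(scope="session")
def open_trefoil():
    """Open trefoil with 20-point straight tails on both sides."""
    chain, spec = sd.open_knot(sd.torus_knot(2, 3, 120), gap=4,
                               tail_n=20, tail_c=20)
    return chain, spec


def quick_params(seed: int, n_closures: int = 25) -> ClosureParams:
    return ClosureParams(n_closures=n_closures, seed=seed)
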