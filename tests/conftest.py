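import warnings

import pytest

from stericrules import fixtures as fx
from stericrules.rulegen import RateParameters

from helpers import uniform_geometry


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # Short-horizon runs in tests may flag the slow redistribution mode;
    # conservation and distribution checks below do not depend on it.
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="steady state", category=UserWarning
        )
        warnings.filterwarnings(
            "ignore", message="bond count", category=UserWarning
        )
        yield


@pytest.fixture(scope="session")
def native_geometry():
    return fx.load_geometry("native")


@pytest.fixture(scope="session")
def chain_adjacency(native_geometry):
    """Nearest-neighbor chain A-B-C-D-E-F on both strands (full resolution)."""
    return tuple(g.build_adjacency(8.0) for g in native_geometry)


@pytest.fixture(scope="session")
def demo_rates():
    return RateParameters(k_f1=1.0, k_f2=0.005, k_r=0.01)


@pytest.fixture()
def single_threshold_geometry():
    return uniform_geometry()
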