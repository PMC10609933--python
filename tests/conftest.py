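import numpy as np
import pytest

from isgel.formulations import REFERENCE_PARAMETERS
from isgel.release_core import FirstOrderModel


@pytest.fixture
def lv20zd_forward() -> FirstOrderModel:
    """Reference model for the fastest-releasing 20% zein/DMSO depot."""
    return FirstOrderModel.from_K32(K32=56.65, C2_edge=103.50, V3=80.0)


@pytest.fixture
def dense_grid() -> np.ndarray:
    """Uniform 0-7 day grid at millistep resolution (forward-scheme runs)."""
    return np.arange(0.0, 7.0 + 5e-4, 0.001)


def pytest_make_parametrize_id(config, val, argname):
    if argname == "row" and isinstance(val, tuple):
        (label, method), _ = val
        return f"{label}-{method}"
    return None


@pytest.fixture(params=sorted(REFERENCE_PARAMETERS.items()))
def row(request):
    """One (formulation, scheme) -> (K32, C2) reference row at a time."""
    return request.param
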