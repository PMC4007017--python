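import numpy as np
import pytest

from bimocon.schedule import generate_schedule
from bimocon.synth import ConnectivityGroundTruth


@pytest.fixture
def default_schedule():
    return generate_schedule()


@pytest.fixture
def chain4_truth():
    """Four-variable causal chain x1 -> x2 -> x3 -> x4."""
    A = np.zeros((4, 4))
    A[1, 0] = 0.6
    A[2, 1] = 0.5
    A[3, 2] = 0.4
    return ConnectivityGroundTruth(
        variables=("x1", "x2", "x3", "x4"),
        path_matrix=A,
        disturbance_var=np.array([1.0, 0.8, 0.9, 1.1]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
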