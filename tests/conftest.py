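import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_subject():
    """Monotone-likelihood toy: x = (1, 0), events at times (1, 2).

    Closed forms: l(b) = b - log(e^b + 1) (strictly increasing, no finite
    MPLE); penalized l*(b) = 1.5 b - 2 log(1 + e^b), maximized at b = log 3.
    """
    time = np.array([2.0, 1.0])
    d = np.array([1, 1], dtype=np.int64)
    X = np.array([[0.0], [1.0]])
    return time, d, X


@pytest.fixture(scope="session")
def rich_scenario():
    """Well-behaved condition: plentiful events in all four cells."""
    from coxinter import Scenario

    return Scenario(n=300, p_M=0.5, p_T=0.5, p_e=0.4, p_c=0.2, t_end=5.0,
                    OR_MT=1.0, HR_M=2.0, HR_T=0.8, HR_I=0.5, N=100,
                    master_seed=12345)
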