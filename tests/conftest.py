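import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def state_sum_rate(P, F, tsat, tbg, alpha=None, beta=1.0):
    """Independent brute-force oracle: explicit Boltzmann-weighted average
    over the promoter state list.

    States (weight, initiation rate):
      unbound        (1, 0)
      TF-bound       (F, 0)
      RNAP-bound     (P, tsat)
      doubly bound   (alpha*F*P, beta*tsat)   -- absent if alpha is None
    """
    states = [(1.0, 0.0), (F, 0.0), (P, tsat)]
    if alpha is not None:
        states.append((alpha * F * P, beta * tsat))
    Z = sum(w for w, _ in states)
    return sum(w * r for w, r in states) / Z + tbg


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
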