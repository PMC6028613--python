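import numpy as np
import pytest

from navsig import ChannelModel, LinearChainScheme, hh_sodium_model
from navsig.rates import RateFunction


@pytest.fixture(scope="session")
def hh_model():
    return hh_sodium_model()


@pytest.fixture(scope="session")
def two_state_scheme():
    """C <=> O with constant rates alpha = 2, beta = 1 (1/ms)."""
    return LinearChainScheme(
        forward=(RateFunction("constant", 2.0),),
        backward=(RateFunction("constant", 1.0),),
    )


@pytest.fixture(scope="session")
def equal_chain6():
    """Six closed states, equal exponentially voltage-dependent rates."""
    fw = tuple(RateFunction("exponential", 3.0, -20.0, 25.0) for _ in range(6))
    bw = tuple(RateFunction("exponential", 0.4, -20.0, -25.0) for _ in range(6))
    return LinearChainScheme(fw, bw)


@pytest.fixture(scope="session")
def chain6_model(equal_chain6):
    return ChannelModel(equal_chain6, g_max=20.0, e_rev=50.0, name="chain6")


def random_chain(rng: np.random.Generator, n_transitions: int,
                 backward: bool = True) -> LinearChainScheme:
    """A chain with log-uniform random constant rates (test helper)."""
    fw = tuple(RateFunction("constant", float(r))
               for r in np.exp(rng.uniform(np.log(0.2), np.log(20.0),
                                           n_transitions)))
    if backward:
        bw = tuple(RateFunction("constant", float(r))
                   for r in np.exp(rng.uniform(np.log(0.05), np.log(5.0),
                                               n_transitions)))
    else:
        bw = tuple(RateFunction("constant", 0.0) for _ in range(n_transitions))
    return LinearChainScheme(fw, bw)
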