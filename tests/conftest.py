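import numpy as np
import pytest

from fibrophase import BASELINE_PARAMS, Environment, ReducedParams


@pytest.fixture(scope="session")
def baseline():
    return BASELINE_PARAMS


@pytest.fixture(scope="session")
def bistable_env():
    """Environment deep enough in the bistable wedge at baseline parameters."""
    return Environment(y=0.1, H=1.33)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230915)


def random_params(rng, n=1, lo=0.1, hi=10.0):
    """Positive parameter draws spanning two decades, log-uniform."""
    draws = [
        ReducedParams(*np.exp(rng.uniform(np.log(lo), np.log(hi), size=5)))
        for _ in range(n)
    ]
    return draws if n > 1 else draws[0]
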