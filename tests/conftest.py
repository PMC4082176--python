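import numpy as np
import pytest

from rosemarkov import HONG_KONG_2012, HONG_KONG_Q0, TransitionParameters


@pytest.fixture
def hk_params() -> TransitionParameters:
    return HONG_KONG_2012


@pytest.fixture
def hk_q0() -> int:
    return HONG_KONG_Q0


def draw_valid_params(rng: np.random.Generator, min_row: float = 0.1) -> TransitionParameters:
    """One random valid parameter set: each living state's three exit
    probabilities are a scaled simplex point, so row sums lie in
    [min_row, 1) and the chain mixes at a testable speed."""
    (p21, p31, p41) = rng.dirichlet([1.0, 1.0, 1.0]) * rng.uniform(min_row, 0.999)
    (p12, p32, p42) = rng.dirichlet([1.0, 1.0, 1.0]) * rng.uniform(min_row, 0.999)
    return TransitionParameters(
        p21=p21, p12=p12, p31=p31, p32=p32, p41=p41, p42=p42
    ).validate()
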