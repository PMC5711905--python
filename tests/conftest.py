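import numpy as np
import pytest

from spad import (
    BetaParams,
    NeutralParams,
    neutral_to_ratespec,
    stationary_beta,
)

# the reference relaxation-experiment parameter set used throughout
REF_M = 0.09
REF_P = 0.0044
REF_LAM = 0.001585


@pytest.fixture(scope="session")
def ref_params() -> NeutralParams:
    return NeutralParams(m=REF_M, p=REF_P, lam=REF_LAM)


@pytest.fixture(scope="session")
def ref_stationary(ref_params) -> BetaParams:
    return stationary_beta(neutral_to_ratespec(ref_params))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
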