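import numpy as np
import pytest

import sirnlme as s
from sirnlme import proposal as prop


@pytest.fixture(scope="session")
def toy():
    """Conjugate toy fixture with its exact estimate and sampling covariance."""
    fx = s.make_fixture("conjugate_toy", seed=3)
    est, cov = fx.model.exact_estimate(fx.data)
    return fx, est, cov


@pytest.fixture(scope="session")
def toy_weighted(toy):
    """A weighted sample on the toy drawn from the exact sampling distribution."""
    fx, est, cov = toy
    p = prop.from_covariance(est, cov)
    drawn = prop.sample(p, 2000, seed=10)
    ref = s.evaluate_ofv(fx.model, fx.data, est)
    return s.weight_sample(fx.model, fx.data, drawn.values, p, ref)


@pytest.fixture(scope="session")
def lm_small():
    return s.make_fixture("linear_mixed_small", seed=1)


@pytest.fixture(scope="session")
def lm_large():
    return s.make_fixture("linear_mixed_large", seed=1)


@pytest.fixture(scope="session")
def lm_large_fit(lm_large):
    return s.estimate_parameters(lm_large.model, lm_large.data)
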