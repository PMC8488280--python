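import numpy as np
import pandas as pd
import pytest

from pairsig import survival as sv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def weibull_ph_data(
    rng,
    n,
    beta=(),
    X=None,
    shape=1.2,
    scale=8500.0,
    cens_upper=5500.0,
):
    """Small Weibull proportional-hazards generator for estimator tests."""
    beta = np.asarray(beta, dtype=float)
    if X is None:
        X = rng.normal(size=(n, len(beta))) if len(beta) else np.zeros((n, 0))
    eta = X @ beta if len(beta) else np.zeros(n)
    t = scale * (rng.exponential(size=n) / np.exp(eta)) ** (1.0 / shape)
    c = rng.uniform(0, cens_upper, size=n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    cov = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    return sv.SurvivalData(time, event, cov if X.shape[1] else None), X
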