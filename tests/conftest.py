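import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ols_oracle(x, y):
    """Closed-form normal-equations OLS, independent of the fitting path."""
    x = np.asarray(x, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, dtype=float))
    return float(beta[0]), float(beta[1])
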