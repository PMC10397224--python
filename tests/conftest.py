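import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr():
    """Tiny two-tissue expression matrix with known tissue means."""
    from craniodev import ExpressionMatrix

    counts = pd.DataFrame(
        {"a1": [2, 0, 5], "a2": [4, 0, 5], "b1": [6, 0, 5]},
        index=["g1", "g2", "g3"],
    )
    tissues = pd.Series({"a1": "A", "a2": "A", "b1": "B"})
    return ExpressionMatrix(counts, tissues)
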