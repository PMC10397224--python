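"""Independent oracle implementations shared by the test suite."""

import math

import numpy as np


def gini_mad(x):
    """Gini via the mean-absolute-difference identity."""
    x = np.asarray(x, dtype=float)
    n = x.size
    return np.abs(x[:, None] - x[None, :]).sum() / (2 * n**2 * x.mean())


def fisher_enum(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration (log-gamma)."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)

    def logpmf(x):
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(n - r1 + 1) - math.lgamma(c1 - x + 1)
            - math.lgamma(n - r1 - c1 + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    probs = [math.exp(logpmf(x)) for x in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-7)))
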