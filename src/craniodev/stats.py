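"""Exact set-overlap and clinical statistics.

Two-sided Fisher exact tests on 2x2 tables (minimum-likelihood
summation over the hypergeometric distribution with fixed margins),
gene-list overlap tests with fold enrichment, exact (Clopper-Pearson)
binomial confidence intervals, and rounded proportions.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

# relative tie tolerance of the minimum-likelihood summation: tables with
# pmf <= pmf_observed * (1 + eps) are counted in the two-sided p
_TIE_EPS = 1e-7


@dataclasses.dataclass
class ContingencyResult:
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_two_sided: float


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Two-tailed Fisher exact test of the table [[a, b], [c, d]].

    p is the sum of hypergeometric probabilities, at fixed margins, of
    every table no more likely than the observed one (relative tie
    tolerance 1e-7).  The unconditional sample odds ratio (a*d)/(b*c) is
    reported; inf on a zero in b or c with a*d > 0, NaN when both
    products vanish.
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError("cells must be nonnegative integers")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_EPS)].sum())
    p = min(p, 1.0)

    ad, bc = a * d, b * c
    if bc > 0:
        oratio = ad / bc
    elif ad > 0:
        oratio = float("inf")
    else:
        oratio = float("nan")
    return ContingencyResult(a, b, c, d, oratio, p)


def gene_overlap_test(list_a, list_b, universe) -> dict:
    """Fisher overlap test of two gene lists within a universe.

    Genes outside the universe are dropped (counts reported).  Fold
    enrichment = |A∩B| * |U| / (|A| * |B|).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    A, B = set(list_a), set(list_b)
    dropped_a, dropped_b = len(A - universe), len(B - universe)
    A &= universe
    B &= universe
    inter = len(A & B)
    table = (inter, len(A - B), len(B - A), len(universe - (A | B)))
    res = fisher_exact_2x2(*table)
    fold = (
        inter * len(universe) / (len(A) * len(B)) if A and B else float("nan")
    )
    return {
        "result": res,
        "fold_enrichment": fold,
        "n_overlap": inter,
        "dropped_a": dropped_a,
        "dropped_b": dropped_b,
    }


@dataclasses.dataclass
class ExactBinomialCI:
    x: int
    n: int
    level: float
    lower: float
    upper: float


def clopper_pearson(x: int, n: int, level: float = 0.95) -> ExactBinomialCI:
    """Exact binomial confidence interval by inverting binomial tail tests.

    L is the beta((1-level)/2; x, n-x+1) quantile, U the
    beta(1-(1-level)/2; x+1, n-x) quantile, with the closed forms L = 0
    at x = 0 and U = 1 at x = n.
    """
    if not (0 <= x <= n) or n < 1:
        raise ValueError("need 0 <= x <= n with n >= 1")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return ExactBinomialCI(x, n, level, lower, upper)


def ci_percent(ci: ExactBinomialCI, decimals: int = 1) -> tuple:
    """Confidence bounds as percentages with outward (conservative) rounding.

    The lower bound is rounded down and the upper bound up at the given
    precision, so the displayed interval always contains the exact one.
    """
    scale = 10.0**decimals
    lo = np.floor(ci.lower * 100 * scale) / scale
    hi = np.ceil(ci.upper * 100 * scale) / scale
    return float(lo), float(hi)


def proportion_percent(x: int, n: int, decimals: int = 0) -> float:
    """100*x/n rounded half-up to ``decimals`` places."""
    if n < 1:
        raise ValueError("n must be >= 1")
    q = Decimal(1).scaleb(-decimals)
    pct = Decimal(100) * Decimal(x) / Decimal(n)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))
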