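"""Tissue-specificity scoring with the Gini index.

A gene's per-tissue mean expression profile is summarised by the Gini
inequality index

    G = (2 * sum_i i * x_(i)) / (n * sum_i x_(i)) - (n + 1) / n

with x_(1) <= ... <= x_(n) the sorted tissue means and n the number of
tissues.  G = 0 for perfectly uniform expression and approaches
(n - 1)/n for expression confined to a single tissue.  Genes with
G >= 0.7 are called tissue-specific and assigned to the tissue of
maximal mean expression.  The biased (population) form above is used
verbatim, with no small-sample correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix, logger


def compute_tissue_means(expr: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean of counts per tissue, genes x tissues.

    Every tissue must have at least one sample.
    """
    tissues = expr.sample_tissue
    counts = tissues.value_counts()
    if (counts == 0).any():
        raise ValueError("tissue with zero samples")
    means = expr.counts.T.groupby(tissues).mean().T
    return means.sort_index(axis=1)


def gini_index(values) -> float:
    """Gini index of a vector of n >= 2 nonnegative tissue means.

    Returns NaN for an all-zero vector (the gene is excluded from
    specific-gene calling).  Invariant under positive rescaling and
    under permutation of the input order.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a vector of at least 2 tissue means")
    if (x < 0).any():
        raise ValueError("negative tissue mean")
    total = x.sum()
    if total == 0:
        return float("nan")
    n = x.size
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    return float(2.0 * (i * xs).sum() / (n * total) - (n + 1) / n)


def gini_index_matrix(means: pd.DataFrame) -> pd.Series:
    """Vectorised Gini over a genes x tissues mean table."""
    x = means.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative tissue mean")
    n = x.shape[1]
    total = x.sum(axis=1)
    xs = np.sort(x, axis=1)
    i = np.arange(1, n + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = 2.0 * (xs * i).sum(axis=1) / (n * total) - (n + 1) / n
    g[total == 0] = np.nan
    return pd.Series(g, index=means.index, name="gini")


def assign_tissue(means: pd.DataFrame) -> pd.DataFrame:
    """Tissue of maximal mean per gene; lexicographic tie-break, flagged.

    All-zero genes get a missing assignment.
    """
    cols = np.array(sorted(means.columns))
    m = means[cols].to_numpy(dtype=float)
    best = m.argmax(axis=1)  # argmax takes the first = lexicographic minimum
    maxval = m[np.arange(len(m)), best]
    tied = (m == maxval[:, None]).sum(axis=1) > 1
    assigned = cols[best].astype(object)
    assigned[maxval == 0] = None
    return pd.DataFrame(
        {"assigned_tissue": assigned, "tie": tied & (maxval > 0)}, index=means.index
    )


def gini_table(expr: ExpressionMatrix, threshold: float = 0.7) -> pd.DataFrame:
    """Per-gene specificity table: gini, assigned tissue, is_specific."""
    means = compute_tissue_means(expr)
    g = gini_index_matrix(means)
    assign = assign_tissue(means)
    out = pd.concat([g, assign], axis=1)
    out["is_specific"] = (out["gini"] >= threshold) & out["assigned_tissue"].notna()
    return out


def call_specific_genes(table: pd.DataFrame, tissue: str, threshold: float = 0.7) -> set:
    """Genes with gini >= threshold assigned to ``tissue`` (inclusive >=)."""
    known = set(table["assigned_tissue"].dropna())
    if tissue not in known:
        raise ValueError(f"unknown tissue label {tissue!r}")
    mask = (table["gini"] >= threshold) & (table["assigned_tissue"] == tissue)
    return set(table.index[mask])


def filter_low_expression(
    expr: ExpressionMatrix, stat: str = "sum", threshold: float = 100.0
) -> ExpressionMatrix:
    """Drop genes whose per-gene ``stat`` over samples is below ``threshold``.

    Genes with stat >= threshold are retained ("lower than" exclusion
    semantics); the removed count is logged.  An empty result is a
    warning, not an error.
    """
    if stat == "sum":
        s = expr.counts.sum(axis=1)
    elif stat == "mean":
        s = expr.counts.mean(axis=1)
    else:
        raise ValueError("stat must be 'sum' or 'mean'")
    keep = s >= threshold
    removed = int((~keep).sum())
    logger.info("filter_low_expression: removed %d of %d genes", removed, len(keep))
    if not keep.any():
        warnings.warn("all genes fall below the expression threshold")
    return ExpressionMatrix(expr.counts.loc[keep], expr.sample_tissue)


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1); zero maps to zero."""
    if (expr.counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return ExpressionMatrix(np.log2(expr.counts + 1.0), expr.sample_tissue)
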