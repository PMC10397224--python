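"""Permutation and resampling enrichment machinery.

Three resampling harnesses share the empirical p-value estimator
p = (1 + m) / (1 + B), with m the number of null draws at least as
extreme as the observed statistic:

* gene-list enrichment per module, nulled by scrambling genes among
  modules of the same number and sizes;
* constraint-decile (LOEUF) enrichment of hub genes, nulled by drawing
  equally many non-hub genes;
* a global protein-interaction harness counting significant modules on
  the real assignment against size-preserving random assignments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import logger


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, order-preserving)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def scramble_modules(labels: pd.Series, rng) -> pd.Series:
    """Uniform random permutation of genes over the same label multiset."""
    rng = np.random.default_rng(rng)
    values = labels.to_numpy().copy()
    rng.shuffle(values)
    return pd.Series(values, index=labels.index, name=labels.name)


def module_list_enrichment(
    labels: pd.Series, gene_lists: dict, B: int = 1000, rng=None, adjust: bool = True
) -> pd.DataFrame:
    """Permutation enrichment of gene lists in modules.

    Observed statistic: |module ∩ list| per module.  Null: B scrambles of
    the gene -> module map.  p = (1+m)/(1+B) per (module, list);
    BH-adjusted across all module x list pairs when ``adjust``.
    List genes absent from the network are dropped (count logged); a
    list with empty intersection is an error.
    """
    rng = np.random.default_rng(rng)
    network_genes = set(labels.index)
    mods = sorted(set(labels) - {0})
    lab = labels.to_numpy()
    n_mods_max = int(lab.max()) + 1

    rows = []
    for list_name, genes in gene_lists.items():
        inside = set(genes) & network_genes
        dropped = len(set(genes)) - len(inside)
        if dropped:
            logger.info("list %s: %d genes absent from the network", list_name, dropped)
        if not inside:
            raise ValueError(f"gene list {list_name!r} has no genes in the network")
        member = labels.index.isin(inside)
        observed = np.bincount(lab[member], minlength=n_mods_max)

        null = np.empty((B, n_mods_max), dtype=np.int64)
        perm = lab.copy()
        for b in range(B):
            rng.shuffle(perm)
            null[b] = np.bincount(perm[member], minlength=n_mods_max)
        for mod in mods:
            m = int((null[:, mod] >= observed[mod]).sum())
            rows.append(
                {
                    "module": mod,
                    "list": list_name,
                    "observed": int(observed[mod]),
                    "null_mean": float(null[:, mod].mean()),
                    "null_sd": float(null[:, mod].std(ddof=1)) if B > 1 else 0.0,
                    "p": (1.0 + m) / (1.0 + B),
                }
            )
    res = pd.DataFrame(rows)
    if adjust:
        res["p_adj"] = bh_adjust(res["p"].to_numpy())
    return res


def hub_loeuf_enrichment(
    hubs, non_hub_pool, deciles: pd.Series, B: int = 1000, rng=None
) -> pd.DataFrame:
    """Constraint-decile enrichment of hub genes against non-hub resamples.

    Observed: per-decile counts among hub genes.  Null: B uniform draws
    of |hubs| genes from the non-hub pool.  Both enrichment and
    depletion empirical p-values are reported.  Genes without a decile
    are dropped from both sides (counts logged).
    """
    rng = np.random.default_rng(rng)
    hubs = sorted(set(hubs))
    pool = sorted(set(non_hub_pool) - set(hubs))
    have = set(deciles.index)
    hubs_d = [g for g in hubs if g in have]
    pool_d = [g for g in pool if g in have]
    if len(hubs_d) < len(hubs) or len(pool_d) < len(pool):
        logger.info(
            "dropped %d hub and %d non-hub genes without a decile",
            len(hubs) - len(hubs_d), len(pool) - len(pool_d),
        )
    if len(pool_d) < len(hubs_d):
        raise ValueError("non-hub pool smaller than hub set")

    dec = deciles.astype(int)
    if not dec.isin(range(1, 11)).all():
        raise ValueError("deciles must be integers in 1..10")
    observed = np.bincount(dec.loc[hubs_d].to_numpy(), minlength=11)[1:]

    pool_dec = dec.loc[pool_d].to_numpy()
    n_draw = len(hubs_d)
    # Gumbel top-k trick: B simultaneous without-replacement samples
    keys = rng.random((B, len(pool_dec)))
    idx = np.argpartition(keys, n_draw - 1, axis=1)[:, :n_draw]
    null = np.stack([np.bincount(pool_dec[row], minlength=11)[1:] for row in idx])

    m_enrich = (null >= observed[None, :]).sum(axis=0)
    m_deplete = (null <= observed[None, :]).sum(axis=0)
    return pd.DataFrame(
        {
            "decile": np.arange(1, 11),
            "observed": observed,
            "null_mean": null.mean(axis=0),
            "null_sd": null.std(axis=0, ddof=1) if B > 1 else np.zeros(10),
            "p_enrich": (1.0 + m_enrich) / (1.0 + B),
            "p_deplete": (1.0 + m_deplete) / (1.0 + B),
        }
    )


def edge_enrichment_test(
    module_genes, edges: pd.DataFrame, universe, max_genes: int = 500, rng=None
) -> float:
    """One-sided binomial test for intra-module interaction-edge excess.

    The null model places each of the universe's edges independently with
    the global edge density over all unordered gene pairs; the observed
    statistic is the number of edges with both endpoints in the module.
    Modules larger than ``max_genes`` are subsampled with the run seed.
    Returns the upper-tail p-value (NaN for an empty universe or edge
    set).
    """
    uni = pd.Index(sorted(set(universe)))
    n_u = len(uni)
    if n_u < 2 or not len(edges):
        return float("nan")
    ea = uni.get_indexer(edges.iloc[:, 0])
    eb = uni.get_indexer(edges.iloc[:, 1])
    keep = (ea >= 0) & (eb >= 0) & (ea != eb)
    ea, eb = ea[keep], eb[keep]
    n_edges = len(ea)
    if n_edges == 0:
        return float("nan")

    gidx = uni.get_indexer(pd.Index(sorted(set(module_genes))))
    gidx = gidx[gidx >= 0]
    if len(gidx) > max_genes:
        rng = np.random.default_rng(rng)
        gidx = rng.choice(gidx, size=max_genes, replace=False)
    member = np.zeros(n_u, dtype=bool)
    member[gidx] = True
    observed = int((member[ea] & member[eb]).sum())

    density = n_edges / (n_u * (n_u - 1) / 2)
    n_pairs = len(gidx) * (len(gidx) - 1) // 2
    if n_pairs == 0:
        return 1.0
    # P(X >= observed) under Binomial(n_pairs, density)
    return float(stats.binom.sf(observed - 1, n_pairs, density))


def ppi_randomization(
    labels: pd.Series,
    edges: pd.DataFrame,
    R: int = 100,
    alpha: float = 0.05,
    max_genes: int = 500,
    rng=None,
) -> dict:
    """Global interaction-enrichment significance of a module assignment.

    Observed: the number of modules whose Bonferroni-adjusted edge
    enrichment p is < alpha.  Null: the same count on R size-preserving
    random assignments.  Permutation p = (1 + m) / (1 + R).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(rng)
    mods = sorted(set(labels) - {0})
    if not mods:
        raise ValueError("no modules in the assignment")
    universe = list(labels.index)

    def count_significant(assign: pd.Series) -> int:
        ps = []
        for mod in mods:
            genes = assign.index[assign == mod]
            ps.append(edge_enrichment_test(genes, edges, universe, max_genes, rng))
        ps = np.array(ps, dtype=float)
        adj = np.minimum(ps * len(mods), 1.0)  # Bonferroni
        return int(np.nansum(adj < alpha))

    observed = count_significant(labels)
    null = np.array([count_significant(scramble_modules(labels, rng)) for _ in range(R)])
    m = int((null >= observed).sum())
    return {
        "observed": observed,
        "null_counts": null,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)) if R > 1 else 0.0,
        "p": (1.0 + m) / (1.0 + R),
        "R": R,
    }
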