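"""Multi-criterion candidate disease-gene prioritization.

A gene is prioritized when it is mutation-constrained (LOEUF decile
<= 3) and carries at least two of three supporting evidence flags:
tissue-specific expression (Gini call), targeting by at least one
tissue-specific enhancer, and coexpression-network hub status.  The
alternative reading "any 2 of the 4 criteria" (constraint counted as a
flag, no hard gate) is available as ``rule="any2of4"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def flag_genes(
    gini_genes,
    enhancer_counts: pd.Series,
    hub_genes,
    deciles: pd.Series,
    min_enhancers: int = 1,
) -> pd.DataFrame:
    """Assemble the per-gene evidence table over the union of inputs.

    Missing evidence is false; a missing decile fails the decile gate.
    """
    gini_genes = set(gini_genes)
    hub_genes = set(hub_genes)
    enhancer_counts = pd.Series(enhancer_counts, dtype=float)
    universe = sorted(
        gini_genes | hub_genes | set(enhancer_counts.index) | set(deciles.index)
    )
    df = pd.DataFrame(index=pd.Index(universe, name="gene_id"))
    df["decile"] = pd.Series(deciles).reindex(universe)
    df["n_enhancers_assigned"] = enhancer_counts.reindex(universe).fillna(0).astype(int)
    df["is_gini"] = df.index.isin(gini_genes)
    df["is_enhancer_target"] = df["n_enhancers_assigned"] >= min_enhancers
    df["is_hub"] = df.index.isin(hub_genes)
    df["n_extra"] = (
        df["is_gini"].astype(int) + df["is_enhancer_target"].astype(int) + df["is_hub"].astype(int)
    )
    return df


def prioritize(
    evidence: pd.DataFrame,
    max_decile: int = 3,
    min_extra_criteria: int = 2,
    rule: str = "gate",
) -> pd.DataFrame:
    """Apply the prioritization rule and return the called genes.

    ``rule="gate"`` (default): decile <= max_decile AND n_extra >=
    min_extra_criteria.  ``rule="any2of4"``: the decile criterion counts
    as a fourth flag and any ``min_extra_criteria`` of the four suffice.
    Output sorted by (n_extra desc, decile asc, gene_id asc).
    """
    ev = evidence.copy()
    decile_ok = ev["decile"].notna() & (ev["decile"] <= max_decile)
    if rule == "gate":
        ev["prioritized"] = decile_ok & (ev["n_extra"] >= min_extra_criteria)
    elif rule == "any2of4":
        ev["prioritized"] = (ev["n_extra"] + decile_ok.astype(int)) >= min_extra_criteria
    else:
        raise ValueError("rule must be 'gate' or 'any2of4'")
    called = ev[ev["prioritized"]].copy()
    called["_dec"] = called["decile"].fillna(np.inf)
    called = called.sort_values(
        ["n_extra", "_dec"], ascending=[False, True], kind="stable"
    ).drop(columns="_dec")
    ev["prioritized"] = ev["prioritized"].astype(bool)
    return called
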