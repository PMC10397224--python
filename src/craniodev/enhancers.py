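"""Tissue-specific enhancer derivation and enhancer-gene linking.

Tissue-specific segments are obtained by base-level subtraction of every
other tissue's segments from the target tissue's segments.  Each
resulting enhancer is linked to the single gene whose TSS is nearest,
within a 1 Mb window (the single-nearest-gene rule).  Distance
convention: 0 if the TSS (a 1-bp interval) overlaps the enhancer,
otherwise the half-open gap length between the TSS interval and the
nearer enhancer edge.  Distance enrichment of enhancers around a target
gene set is assessed against a permutation null drawn from a background
gene pool.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_core import segment_set
from .enrichment import bh_adjust


# ---------------------------------------------------------------------------
# Segment subtraction
# ---------------------------------------------------------------------------


def _union_intervals(starts: np.ndarray, ends: np.ndarray):
    """Merge possibly-overlapping intervals into a disjoint sorted union."""
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [], []
    for s, e in zip(starts, ends):
        if out_e and s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def subtract_segments(
    target: pd.DataFrame,
    others: list,
    min_residual: int = 1,
    mode: str = "subtract",
) -> pd.DataFrame:
    """Remove bases of ``target`` covered by any segment in ``others``.

    ``mode="subtract"`` (default) keeps the uncovered residual pieces of
    each target segment, dropping residuals shorter than ``min_residual``
    bp; residual names carry a ``/k`` suffix when a segment splits.
    ``mode="exclude"`` instead drops any target segment with any overlap
    (whole-segment exclusion).  Output never overlaps any ``others`` base.
    """
    if not len(target):
        return segment_set([])
    frames = [o for o in others if len(o)]
    if not frames:
        return target.reset_index(drop=True)
    other = pd.concat(frames, ignore_index=True)

    rows = []
    for chrom, tgt in target.groupby("chrom", sort=False):
        oc = other[other["chrom"] == chrom]
        if not len(oc):
            rows.extend(tgt.itertuples(index=False))
            continue
        us, ue = _union_intervals(oc["start"].to_numpy(), oc["end"].to_numpy())
        for rec in tgt.itertuples(index=False):
            # union intervals overlapping [rec.start, rec.end)
            lo = np.searchsorted(ue, rec.start, side="right")
            hi = np.searchsorted(us, rec.end, side="left")
            if lo >= hi:
                rows.append(rec)
                continue
            if mode == "exclude":
                continue
            pieces = []
            cursor = rec.start
            for s, e in zip(us[lo:hi], ue[lo:hi]):
                if s > cursor:
                    pieces.append((cursor, min(s, rec.end)))
                cursor = max(cursor, e)
            if cursor < rec.end:
                pieces.append((cursor, rec.end))
            pieces = [(s, e) for s, e in pieces if e - s >= min_residual]
            for k, (s, e) in enumerate(pieces):
                name = rec.name if len(pieces) == 1 else f"{rec.name}/{k}"
                rows.append((chrom, s, e, name))
    if mode == "exclude":
        return segment_set([(r.chrom, r.start, r.end, r.name) for r in rows])
    out = []
    for r in rows:
        if isinstance(r, tuple):
            out.append(r)
        else:
            out.append((r.chrom, r.start, r.end, r.name))
    return segment_set(out)


# ---------------------------------------------------------------------------
# Enhancer-gene distance and linking
# ---------------------------------------------------------------------------


def _tss_distance(starts, ends, tss):
    """Vectorised gap distance between enhancers and a matrix of TSSs.

    ``starts``/``ends`` shape (m,), ``tss`` shape (k,).  Returns (m, k).
    TSS occupies [t, t+1); 0 on overlap, else the half-open gap length.
    """
    t = np.asarray(tss)[None, :]
    s = np.asarray(starts)[:, None]
    e = np.asarray(ends)[:, None]
    left = s - t - 1  # TSS entirely before the enhancer
    right = t - e  # TSS at or after the enhancer end
    d = np.where(t < s, left, np.where(t >= e, right, 0))
    return d


def nearest_tss_within(
    segments: pd.DataFrame,
    annotation: pd.DataFrame,
    max_link_distance: int = 1_000_000,
) -> pd.DataFrame:
    """Assign each enhancer to its single nearest TSS within the window.

    Ties are broken by lexicographically smaller gene_id.  Enhancers with
    no TSS on their chromosome, or none within ``max_link_distance``, are
    left unassigned (gene_id NA, distance NA).
    """
    if not len(annotation):
        raise ValueError("empty annotation")
    ann = annotation.sort_values(["chrom", "tss", "gene_id"], kind="stable")
    out_gene = np.full(len(segments), None, dtype=object)
    out_dist = np.full(len(segments), np.nan)
    for chrom, grp in ann.groupby("chrom", sort=False):
        mask = (segments["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        seg = segments.loc[mask]
        d = _tss_distance(seg["start"].to_numpy(), seg["end"].to_numpy(), grp["tss"].to_numpy())
        # minimal distance; ties resolved by smaller gene_id
        genes = grp["gene_id"].to_numpy()
        gene_order = np.argsort(genes, kind="stable")
        d_sorted = d[:, gene_order]
        best = d_sorted.argmin(axis=1)  # first minimum = smallest gene_id
        dist = d_sorted[np.arange(len(seg)), best]
        gene = genes[gene_order][best]
        ok = dist <= max_link_distance
        idx = np.flatnonzero(mask)
        out_gene[idx[ok]] = gene[ok]
        out_dist[idx[ok]] = dist[ok]
    res = segments.copy()
    res["gene_id"] = out_gene
    res["distance"] = out_dist
    return res


def count_enhancers_per_gene(assignments: pd.DataFrame) -> pd.Series:
    """Number of assigned enhancers per gene (unassigned rows excluded)."""
    assigned = assignments.dropna(subset=["gene_id"])
    return assigned.groupby("gene_id").size().astype(int)


def closest_gene_distance(
    segments: pd.DataFrame, gene_subset, annotation: pd.DataFrame
) -> pd.Series:
    """Per enhancer, distance to the closest TSS of ``gene_subset``.

    Infinite when the enhancer's chromosome has no subset TSS.
    """
    subset = annotation[annotation["gene_id"].isin(set(gene_subset))]
    if not len(subset):
        raise ValueError("gene_subset has no annotated genes")
    out = np.full(len(segments), np.inf)
    for chrom, grp in subset.groupby("chrom", sort=False):
        mask = (segments["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        seg = segments.loc[mask]
        d = _tss_distance(seg["start"].to_numpy(), seg["end"].to_numpy(), grp["tss"].to_numpy())
        out[mask] = d.min(axis=1)
    return pd.Series(out, index=segments["name"].to_numpy(), name="distance")


def _distance_histogram(dist: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Histogram with a final open-ended overflow bin so finite distances
    are conserved."""
    finite = dist[np.isfinite(dist)]
    counts, _ = np.histogram(finite, bins=np.r_[edges, np.inf])
    return counts


def distance_enrichment_test(
    segments: pd.DataFrame,
    target_genes,
    background_pool,
    annotation: pd.DataFrame,
    B: int = 1000,
    bin_width: int = 20_000,
    max_distance: int = 1_000_000,
    rng=None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Permutation test of enhancer proximity to a target gene set.

    Observed: histogram of each enhancer's closest distance to a target
    TSS (bins of ``bin_width`` from 0 to ``max_distance`` plus one
    overflow bin).  Null: B draws of ``len(target_genes)`` genes from the
    background pool, without replacement, re-histogrammed.  Per-bin
    empirical p = (1 + #{null >= observed}) / (B + 1), optionally
    BH-adjusted across bins.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(rng)
    target_genes = sorted(set(target_genes))
    pool = np.array(sorted(set(background_pool)))
    if len(pool) < len(target_genes):
        raise ValueError("background pool smaller than target set")

    edges = np.arange(0, max_distance + bin_width, bin_width)
    obs_dist = closest_gene_distance(segments, target_genes, annotation).to_numpy()
    observed = _distance_histogram(obs_dist, edges)

    null = np.empty((B, len(observed)), dtype=np.int64)
    for b in range(B):
        draw = rng.choice(pool, size=len(target_genes), replace=False)
        d = closest_gene_distance(segments, draw, annotation).to_numpy()
        null[b] = _distance_histogram(d, edges)

    m = (null >= observed[None, :]).sum(axis=0)
    p = (1.0 + m) / (B + 1.0)
    res = pd.DataFrame(
        {
            "bin_start": np.r_[edges[:-1], edges[-1]],
            "bin_end": np.r_[edges[1:], np.iinfo(np.int64).max],
            "observed": observed,
            "null_mean": null.mean(axis=0),
            "null_sd": null.std(axis=0, ddof=1) if B > 1 else np.zeros_like(p),
            "p": p,
        }
    )
    if adjust:
        res["p_adj"] = bh_adjust(res["p"].to_numpy())
    return res


def median_pair_distance(distances, cutoff: int = 400_000) -> float:
    """Median of assignment distances at or below ``cutoff`` bp.

    NaN when no distance qualifies.
    """
    d = np.asarray(pd.Series(distances).dropna(), dtype=float)
    d = d[d <= cutoff]
    if d.size == 0:
        return float("nan")
    return float(np.median(d))
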