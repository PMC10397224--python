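"""Synthetic data with the statistical structure the pipeline assumes.

Stands in for restricted embryonic expression data and consortium
epigenomes.  Generates (a) multi-tissue negative-binomial counts with
planted tissue-specific genes, (b) a synthetic chromosome with TSS
annotation and enhancer intervals planted near specific-gene TSSs,
(c) a latent-factor timecourse with planted coexpression modules and
hub genes, (d) constraint deciles enriched in planted hubs, (e) gene
lists enriched in planted-truth genes, and (f) interaction edge lists
with intra-module edge excess.  Every generator is deterministic under
a fixed seed and returns a truth object sufficient to score the
corresponding pipeline stage.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Set

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix, segment_set, validate_annotation


@dataclasses.dataclass
class SimParams:
    """Generator parameters (the simulated study conditions).

    Counts follow a gamma-Poisson (negative binomial) model with a
    single dispersion; each tissue-specific gene has its mean multiplied
    by ``fold_specific`` in exactly one tissue.  Enhancers are planted
    within ``planted_distance_max`` bp of specific-gene TSSs on one
    synthetic chromosome.  Timecourse modules are latent smooth factors
    with gene loadings; planted hubs carry the highest loadings.
    """

    n_tissues: int = 10
    samples_per_tissue: int = 4
    n_genes: int = 2000
    frac_specific: float = 0.05
    fold_specific: float = 50.0
    nb_dispersion: float = 0.1
    genome_length: int = 50_000_000
    n_enhancers: int = 300
    planted_distance_max: int = 50_000
    frac_planted_enhancers: float = 0.5
    n_timepoints: int = 17
    n_modules: int = 5
    module_snr: float = 4.0
    hub_fraction: float = 0.10
    decile_hub_enrichment: float = 5.0
    n_list_genes: int = 200
    list_enrichment: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_tissues, self.samples_per_tissue, self.n_genes,
               self.n_timepoints, self.n_modules, self.n_enhancers + 1) < 1:
            raise ValueError("counts must be positive")
        if not (0 < self.frac_specific < 1):
            raise ValueError("frac_specific must be in (0,1)")
        if self.fold_specific < 1:
            raise ValueError("fold_specific must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be nonnegative")


@dataclasses.dataclass
class SimTruth:
    """Ground truth for scoring every downstream stage."""

    specific_genes: Dict[str, Set[str]] = dataclasses.field(default_factory=dict)
    planted_enhancer_gene: Dict[str, Optional[str]] = dataclasses.field(default_factory=dict)
    module_labels_true: Dict[str, int] = dataclasses.field(default_factory=dict)
    hub_genes_true: Set[str] = dataclasses.field(default_factory=set)
    decile_true: Dict[str, int] = dataclasses.field(default_factory=dict)
    enriched_lists: Dict[str, Set[str]] = dataclasses.field(default_factory=dict)


def _nb_counts(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draws with var = mu + dispersion * mu^2."""
    if dispersion == 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu / shape)
    return rng.poisson(lam)


def _gene_ids(n: int):
    return [f"g{i:05d}" for i in range(n)]


def _tissue_labels(n: int):
    return [f"tissue{t:02d}" for t in range(n)]


def simulate_multitissue_counts(params: SimParams, rng=None):
    """Multi-tissue count panel with planted tissue-specific genes.

    Housekeeping genes share one log-normal mean across tissues;
    specific genes have that mean multiplied by ``fold_specific`` in
    exactly one tissue, assigned round-robin.  Returns
    (ExpressionMatrix, SimTruth).
    """
    rng = np.random.default_rng(params.seed if rng is None else rng)
    n_spec = int(round(params.n_genes * params.frac_specific))
    if n_spec < params.n_tissues:
        raise ValueError("n_genes * frac_specific must cover >= 1 gene per tissue")
    genes = _gene_ids(params.n_genes)
    tissues = _tissue_labels(params.n_tissues)

    base_mu = rng.lognormal(mean=np.log(20.0), sigma=1.0, size=params.n_genes)
    mu = np.tile(base_mu[:, None], (1, params.n_tissues))  # genes x tissues

    spec_idx = rng.choice(params.n_genes, size=n_spec, replace=False)
    truth = SimTruth(specific_genes={t: set() for t in tissues})
    for j, gi in enumerate(spec_idx):
        t = j % params.n_tissues
        mu[gi, t] *= params.fold_specific
        truth.specific_genes[tissues[t]].add(genes[gi])

    sample_ids, sample_tissue = [], {}
    cols = []
    for t, tis in enumerate(tissues):
        m = np.tile(mu[:, t][:, None], (1, params.samples_per_tissue))
        cols.append(_nb_counts(rng, m, params.nb_dispersion))
        for s in range(params.samples_per_tissue):
            sid = f"{tis}_s{s}"
            sample_ids.append(sid)
            sample_tissue[sid] = tis
    counts = pd.DataFrame(np.hstack(cols), index=genes, columns=sample_ids)
    return ExpressionMatrix(counts, pd.Series(sample_tissue)), truth


def simulate_annotation_and_enhancers(
    params: SimParams, truth: SimTruth, rng=None, target_tissue: str | None = None
):
    """TSS annotation plus enhancer intervals on one synthetic chromosome.

    A fraction ``frac_planted_enhancers`` of enhancers is placed within
    ``planted_distance_max`` bp of a specific-gene TSS of the target
    tissue (uniform offset, either side); the rest are uniform
    background.  No enhancer overlaps a TSS interval.  Returns
    (annotation, segments, truth).
    """
    rng = np.random.default_rng(params.seed + 1 if rng is None else rng)
    if not truth.specific_genes:
        raise ValueError("truth lacks specific_genes")
    if target_tissue is None:
        target_tissue = sorted(truth.specific_genes)[0]
    genes = sorted({g for s in truth.specific_genes.values() for g in s})
    all_genes = _gene_ids(params.n_genes)

    enh_len = 500
    if params.n_enhancers * enh_len * 10 > params.genome_length:
        raise ValueError("genome too small for the requested enhancer density")

    tss = np.sort(rng.choice(params.genome_length, size=params.n_genes, replace=False))
    order = rng.permutation(params.n_genes)
    ann = validate_annotation(
        pd.DataFrame(
            {
                "gene_id": all_genes,
                "chrom": "chr1",
                "tss": tss[order],
                "strand": rng.choice(["+", "-"], size=params.n_genes),
            }
        )
    )
    tss_by_gene = dict(zip(ann["gene_id"], ann["tss"]))
    tss_set = set(ann["tss"].tolist())
    target_genes = sorted(truth.specific_genes[target_tissue])

    n_planted = int(round(params.n_enhancers * params.frac_planted_enhancers))
    if n_planted and not target_genes:
        raise ValueError(f"no specific genes for tissue {target_tissue!r}")
    rows = []
    for i in range(params.n_enhancers):
        name = f"enh{i:05d}"
        planted_gene = None
        for _ in range(1000):
            if i < n_planted:
                g = target_genes[int(rng.integers(len(target_genes)))]
                offset = int(rng.integers(1, params.planted_distance_max + 1))
                side = 1 if rng.random() < 0.5 else -1
                start = tss_by_gene[g] + side * offset
                planted_gene = g
            else:
                start = int(rng.integers(params.genome_length - enh_len))
            start = int(np.clip(start, 0, params.genome_length - enh_len))
            end = start + enh_len
            if not any(t in tss_set for t in range(start, end)):
                break
        rows.append(("chr1", start, end, name))
        truth.planted_enhancer_gene[name] = planted_gene
    return ann, segment_set(rows), truth


def _module_factor(rng, t: np.ndarray, shape: int) -> np.ndarray:
    """Smooth latent trajectory: increasing, decreasing, or oscillating."""
    if shape == 0:
        f = t + 0.5 * rng.normal() * t**2 + 0.4 * np.sin(np.pi * (t + rng.random()))
    elif shape == 1:
        f = -t - 0.5 * rng.normal() * t**2 + 0.4 * np.sin(np.pi * (t + rng.random()))
    else:
        freq = 1.0 + 1.5 * rng.random()
        f = np.sin(2 * np.pi * (freq * t + rng.random()))
    f = f - f.mean()
    return f / f.std()


def _distinct_factors(rng, t: np.ndarray, n_modules: int, max_cor: float = 0.4):
    """Draw module factors, rejecting positively collinear draws.

    One increasing, one decreasing, the rest oscillating at distinct
    frequencies.  Strong positive factor correlation would make planted
    modules unidentifiable in a signed network (the eigengene-merge step
    would rightly fuse them); negative correlation is harmless there, so
    only positive correlation is bounded.
    """
    factors = []
    for m in range(n_modules):
        shape = m if m < 2 else 2
        for _ in range(500):
            f = _module_factor(rng, t, shape)
            if all(np.corrcoef(f, g)[0, 1] < max_cor for g in factors):
                break
        else:
            raise ValueError("cannot draw sufficiently distinct module factors")
        factors.append(f)
    return factors


def simulate_module_expression(params: SimParams, rng=None, min_module_size: int = 2):
    """Timecourse counts with planted coexpression modules and hubs.

    Per module, a smooth latent factor over timepoints; gene expression
    in log2 space = baseline + loading * factor + noise with
    sd(noise) = loading / module_snr, exponentiated to counts.  The top
    ``hub_fraction`` of each module by loading are the planted hubs.
    Returns (ExpressionMatrix, SimTruth).
    """
    rng = np.random.default_rng(params.seed + 2 if rng is None else rng)
    if params.n_modules < 2:
        raise ValueError("n_modules must be >= 2")
    size = params.n_genes // params.n_modules
    if size < min_module_size:
        raise ValueError("module size below min_module_size")
    genes = _gene_ids(params.n_genes)
    t = np.linspace(0.0, 1.0, params.n_timepoints)
    samples = [f"tp{i:02d}" for i in range(params.n_timepoints)]

    truth = SimTruth()
    expr = np.empty((params.n_genes, params.n_timepoints))
    factors = _distinct_factors(rng, t, params.n_modules)
    g0 = 0
    for m in range(params.n_modules):
        members = genes[g0 : g0 + size] if m < params.n_modules - 1 else genes[g0:]
        k = len(members)
        f = factors[m]
        n_hub = max(1, int(round(params.hub_fraction * k)))
        loadings = rng.uniform(0.4, 0.8, size=k)
        hub_positions = rng.choice(k, size=n_hub, replace=False)
        loadings[hub_positions] = rng.uniform(0.9, 1.0, size=n_hub)
        base = rng.normal(5.0, 1.0, size=k)
        noise = rng.normal(size=(k, params.n_timepoints)) * (
            loadings[:, None] / params.module_snr
        )
        block = base[:, None] + loadings[:, None] * f[None, :] + noise
        expr[g0 : g0 + k] = block
        for pos, gene in enumerate(members):
            truth.module_labels_true[gene] = m + 1
        for pos in hub_positions:
            truth.hub_genes_true.add(members[pos])
        g0 += k

    counts = np.rint(np.clip(2.0**expr - 1.0, 0, None)).astype(np.int64)
    em = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples),
        pd.Series({s: s for s in samples}),
    )
    return em, truth


def simulate_constraint_and_lists(params: SimParams, truth: SimTruth, rng=None):
    """Constraint deciles and enriched gene lists keyed to planted truth.

    Non-hub genes get a uniform decile 1..10; planted hubs get odds of
    deciles 1-3 multiplied by ``decile_hub_enrichment``.  "disease" and
    "dnm" lists are sampled with ``list_enrichment``-fold odds on
    planted-truth genes (hubs plus specific genes).  Returns
    (deciles Series, lists dict, truth).
    """
    rng = np.random.default_rng(params.seed + 3 if rng is None else rng)
    genes = sorted(
        set(truth.module_labels_true)
        | {g for s in truth.specific_genes.values() for g in s}
        | truth.hub_genes_true
    ) or _gene_ids(params.n_genes)

    w_hub = np.ones(10)
    w_hub[:3] *= params.decile_hub_enrichment
    w_hub /= w_hub.sum()
    deciles = {}
    for g in genes:
        if g in truth.hub_genes_true:
            deciles[g] = int(rng.choice(10, p=w_hub)) + 1
        else:
            deciles[g] = int(rng.integers(10)) + 1
    truth.decile_true = deciles
    dec = pd.Series(deciles, name="decile")

    truth_pool = truth.hub_genes_true | {
        g for s in truth.specific_genes.values() for g in s
    }
    weights = np.array(
        [params.list_enrichment if g in truth_pool else 1.0 for g in genes]
    )
    weights /= weights.sum()
    n_list = min(params.n_list_genes, len(genes))
    if n_list < 1:
        raise ValueError("list parameters produce an empty list")
    lists = {}
    for name in ("disease", "dnm"):
        picked = rng.choice(genes, size=n_list, replace=False, p=weights)
        lists[name] = set(picked)
        truth.enriched_lists[name] = set(picked)
    return dec, lists, truth


def simulate_interactions(
    params: SimParams,
    truth: SimTruth,
    rng=None,
    intra_edge_prob: float = 0.02,
    inter_edge_prob: float = 0.001,
):
    """Undirected interaction edges with intra-module edge excess.

    Within-module gene pairs carry an edge with ``intra_edge_prob``,
    all other pairs with ``inter_edge_prob``.  Returns an edge DataFrame
    (gene_a, gene_b).
    """
    rng = np.random.default_rng(params.seed + 4 if rng is None else rng)
    genes = sorted(truth.module_labels_true)
    if not genes:
        raise ValueError("truth lacks module labels")
    lab = np.array([truth.module_labels_true[g] for g in genes])
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    same = lab[iu] == lab[ju]
    p = np.where(same, intra_edge_prob, inter_edge_prob)
    keep = rng.random(len(p)) < p
    garr = np.array(genes)
    return pd.DataFrame({"gene_a": garr[iu[keep]], "gene_b": garr[ju[keep]]})
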