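# Methods

## Tissue-specificity (Gini index)

For gene g with per-tissue mean raw counts `x_1..x_n` (arithmetic mean of
samples per tissue, n >= 2), the score is the biased (population) Gini
index computed on the sorted means:

    G = (2 * sum_i i * x_(i)) / (n * sum_i x_(i)) - (n + 1) / n

No small-sample correction is applied, so the maximum attainable score is
`(n-1)/n` (0.97 for n = 34 tissues). The score is invariant to positive
rescaling and to input order, and equals the mean-absolute-difference
form `sum_ij |x_i - x_j| / (2 n^2 mean)` (used as the test oracle).
All-zero genes get a missing score and are excluded from calling; ties in
the tissue assignment are broken lexicographically and flagged. The call
threshold defaults to `G >= 0.7` (inclusive). Expression filtering keeps
genes whose per-gene sum (or mean) is at least the threshold — i.e.
"lower than" exclusion semantics — with defaults sum >= 100; the log
transform is `log2(x + 1)`. Tissue means are taken on the matrix as
provided: library-size scaling is assumed upstream, with an optional
counts-per-million flag deliberately left off by default.

## Enhancer derivation and linking

Coordinates are 0-based half-open throughout (BED convention), converted
at the boundary if an input is 1-based. Tissue-specific segments are the
residual pieces of target-tissue segments after removing every base
covered by any other tissue's segments (`min_residual` 1 bp by default;
a whole-segment-exclusion mode is available because the derivation rule
admits both readings — subtraction is the default since it preserves
partial specificity).

Distance convention: a TSS is a 1-bp interval `[t, t+1)`; distance is 0
when it overlaps the enhancer, otherwise the half-open gap to the nearer
edge (`start - t - 1` on the left, `t - end` on the right). Each enhancer
links to the single gene minimizing this distance, unassigned beyond
1 Mb; nearest-gene ties break to the lexicographically smaller gene id.

The distance-enrichment test histograms each enhancer's closest distance
to the target gene set in 20 kb bins from 0 to 1 Mb, plus one open-ended
overflow bin so counts conserve. The null redraws `|targets|` genes from
the background pool (which excludes target-tissue genes) without
replacement, B = 1000 times. Per bin, `p = (1 + m)/(1 + B)` with m the
null draws with count >= observed; BH adjustment across bins is on by
default. Median enhancer–gene distance is reported over assigned pairs
within 400 kb. Each enhancer contributes its single closest distance (the
histogram counts enhancers, not pairs).

## Coexpression network

Input is the log2(x+1) matrix after low-expression filtering; constant
genes are dropped with a warning. Signed adjacency
`a_ij = ((1 + cor_ij)/2)^beta` with Pearson correlation and `beta = 18`
(the standard signed-network recommendation for fewer than 20 samples);
the scale-free fit R^2 diagnostic (log10 p(k) vs log10 k over 10
equal-width connectivity bins) supports the power choice. The unsigned
topological overlap

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)

is used on the signed adjacency (the conventional default; no variant is
singled out by the problem). Modules are branches of the average-linkage
tree of `1 - TOM`, cut statically at 0.995 x the maximal merge height and
filtered to a minimum size of 100; smaller branches are unassigned
(label 0). This static-cut-plus-size-filter is a deliberate
simplification of the adaptive hybrid tree cut: it is
parameter-compatible at the interface (`min_module_size`, a cut-height
knob) and sufficient for block-structured dissimilarities, at the cost of
the adaptive algorithm's sensitivity to nested substructure.

Module eigengenes are the unit-norm first right singular vector of the
member-standardized expression, sign-aligned with the module mean
profile. Merging is iterative: while the closest eigengene pair has
dissimilarity `1 - cor < 0.18`, merge it and recompute eigengenes; the
fixed point has all pairwise dissimilarities >= 0.18. Connectivity:
`kTotal_i = sum_j a_ij (j != i)`, `kWithin` restricted to same-module
partners (0 for unassigned genes). Hubs are the top `ceil(0.10 * n)`
genes by `kWithin` network-wide — reproducing 2663 of 26,626 — with
boundary ties broken by kTotal then gene id; per-module and
kTotal-ranked variants are options (under kWithin ranking unassigned
genes effectively cannot be hubs; under kTotal they can). The module
graph connects module pairs with eigengene Pearson correlation >= 0.5
(inclusive, positive only).

## Permutation enrichment

All resampling harnesses share the estimator `p = (1 + m)/(1 + B)`,
which is never below `1/(B + 1)` and reproduces a printed two-decimal
0.01 at B = 100 when the observed statistic exceeds every null draw.

* **Gene-list enrichment.** Observed `|module ∩ list|` per module; null
  from uniform scrambles of genes over the same module-size multiset
  (sizes preserved exactly). The scramble null mean matches the
  hypergeometric expectation `|list| * size_m / n`. BH adjustment spans
  all module x list pairs in a run (per-list adjustment by flag).
* **Hub constraint-decile enrichment.** Observed per-decile counts among
  hubs; null from B uniform draws of `|hubs|` non-hub genes (Gumbel
  top-k sampling, all draws vectorised). Genes without a decile are
  dropped from both sides. Enrichment and depletion tails are both
  reported because constrained deciles enrich while tolerant deciles
  deplete.
* **Interaction (PPI) harness.** Per module, a one-sided binomial test of
  the internal edge count against the global edge density over all
  unordered universe pairs; modules above 500 genes are subsampled with
  the run seed. The global statistic is the number of modules passing
  Bonferroni-adjusted p < 0.05, compared against R = 100 size-preserving
  random assignments. The binomial density null (rather than a
  degree-preserving rewiring null) is a documented simplification; the
  outer permutation layer is exchangeable regardless, so the permutation
  p-value remains valid, and a degree-aware null is a natural extension
  point.

## Prioritization

Default rule: LOEUF decile <= 3 (missing decile fails the gate) AND at
least two of {Gini call, >= 1 specific enhancer assigned, hub}. The
alternative reading — any two of the four criteria with no hard gate —
is available as `rule="any2of4"`; the gate form is the default because it
is the operational description of the procedure. `min_enhancers` defaults to
1 and is configurable (>= 3 is a meaningful stricter variant). Output is
sorted by evidence count, then decile, then gene id.

## Exact statistics

Two-sided Fisher p is the minimum-likelihood summation over the
hypergeometric support at fixed margins, counting tables with
`pmf <= pmf_obs * (1 + 1e-7)` (the relative tie tolerance of the common
calculators); the reported odds ratio is the unconditional sample
`(a d)/(b c)` (inf when only `b c = 0`, NaN when both products vanish).
Gene-overlap tests form the 2x2 table within an explicit universe and
report fold enrichment `|A ∩ B| |U| / (|A| |B|)`. Clopper–Pearson bounds
are beta quantiles — `L = B(alpha/2; x, n-x+1)`, `U = B(1-alpha/2; x+1,
n-x)` — with closed forms at x = 0 and x = n. For display, `ci_percent`
rounds the interval outward (floor the lower bound, ceil the upper) so
the printed interval always contains the exact one; proportions round
half-up. Population-rate comparisons (for example against an assumed
1:500 background rate) are not given a canonical 2x2 construction here,
because finite pseudo-cohort and large-population constructions give
different p-values; only explicit tables are accepted.

## Synthetic data generator

The generator produces the statistical structure each stage assumes, not
realistic genomes: one synthetic chromosome, no isoforms, no batch
effects, no library-size variation, no cell-type mixture. Passing tests
therefore demonstrate correct recovery of planted structure under the
stated models, not performance on real embryonic data.

* **Multi-tissue counts.** Gamma-Poisson (negative binomial) with a
  single dispersion (`var = mu + 0.1 mu^2`), per-gene log-normal baseline
  means (`meanlog = log 20`, `sdlog = 1`); defaults 10 tissues x 4
  samples, 2000 genes, 5% specific genes with a 50-fold mean multiplier
  in exactly one tissue (round-robin assignment).
* **Annotation and enhancers.** TSSs uniform on a 50 Mb chromosome; 300
  enhancers of 500 bp, half placed within 50 kb of a target-tissue
  specific-gene TSS (uniform offset, either side), half uniform
  background; enhancers never overlap a TSS base.
* **Timecourse modules.** 17 timepoints; one increasing, one decreasing,
  and otherwise oscillating latent factors, redrawn until pairwise
  positive correlation is below 0.4 — negative correlation is left
  unbounded because a signed network separates anti-correlated modules,
  while strongly positively correlated factors would make the planted
  partition genuinely unidentifiable (the eigengene merge would rightly
  fuse them). Gene loadings are uniform 0.4–0.8, with the planted hubs
  (10% per module) at 0.9–1.0; noise sd is loading/SNR with SNR 4, and
  log2 expression is exponentiated and rounded to counts.
* **Constraint and lists.** Uniform deciles 1–10 for non-hubs; planted
  hubs get 5-fold odds on deciles 1–3. Disease/DNM-style lists of 200
  genes are drawn with 5-fold odds on planted-truth genes. Interaction
  edges: within-module pair probability 0.02, between 0.001.

Every generator is deterministic under its seed, and the truth object
carries everything needed to score sensitivity/specificity, ARI, and
enrichment without re-simulation.

## Numerical and testing choices

Problem sizes in the test suite are chosen for calibration validity:
null-uniformity checks on empirical p-values must respect their discrete
lattice, so the hub-decile Kolmogorov–Smirnov check uses 300 hubs in
3000 genes (per-decile count pmf well below the KS critical distance at
50 samples per decile) and is applied per decile rather than pooled —
pooled p-values from tied discrete counts are super-uniform by
construction and would fail a naive KS even under a perfect null. The
distance-enrichment null calibration pools 51 bins x 50 seeds and
accepts a rejection fraction of 0.05 +/- 0.04, the discreteness of small
bin counts making the test conservative. Recovery criteria
(sensitivity/FPR, ARI) are assessed as means over 20 fixed seeds.
Degenerate inputs are handled explicitly: empty segment sets, all-zero
genes, constant modules (error), single-module networks (no merge), and
empty histogram bins (overflow bin conserves counts).

## Known limitations

The static module cut can miss nested module structure that the adaptive
hybrid cut would resolve; the interaction null ignores degree
heterogeneity; the Fisher odds ratio is the sample estimator, not the
conditional MLE; coordinate lift-over between assemblies is out of scope
(one assembly per run); and the generator's simplifications listed above
bound what the recovery tests can claim about real data.
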