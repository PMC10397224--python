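# craniodev

Integrative gene prioritization for developmental tissue transcriptomics.

Identifying genes that drive tissue-specific developmental programs — and
that cause congenital disorders such as orofacial clefting when mutated —
requires combining several independent layers of genomic evidence. This
package implements that integration as a tested, reusable pipeline for
bulk RNA-seq count matrices, chromatin-derived enhancer intervals, gene
constraint tables, and curated gene lists:

1. **Tissue-specificity scoring.** For each gene the Gini inequality index
   is computed over its per-tissue mean expression
   `x_(1) <= ... <= x_(n)`:

   `G = (2 * sum_i i * x_(i)) / (n * sum_i x_(i)) - (n + 1) / n`

   `G = 0` means uniform expression; `G -> (n-1)/n` means expression
   confined to one tissue. Genes with `G >= 0.7` are called
   tissue-specific and assigned to the tissue of maximal mean.
2. **Tissue-specific enhancers and linking.** Enhancer segments unique to
   the target tissue are derived by base-level subtraction of all other
   tissues' segments; each enhancer is assigned to the single nearest TSS
   within 1 Mb, and proximity of enhancers to a target gene set is tested
   against a permutation null over background gene draws (B = 1000).
3. **Signed coexpression network.** Adjacency
   `a_ij = ((1 + cor_ij)/2)^beta` with soft power `beta = 18`, topological
   overlap, average-linkage module detection (minimum module size 100),
   eigengene merging at height 0.18, intramodular connectivity `kWithin`,
   and hub calling as the top 10% of connectivity (ceil rule: 2663 hubs in
   a 26,626-gene network).
4. **Permutation enrichment.** Gene-list enrichment per module via
   size-preserving module scrambles; constraint (LOEUF) decile enrichment
   of hubs via non-hub resampling; a global protein-interaction harness
   comparing the count of interaction-enriched modules against 100
   randomized assignments. All empirical p-values use `(1+m)/(1+B)`.
5. **Prioritization.** A gene is a disease-gene candidate when its LOEUF
   decile is <= 3 and it meets at least two of: tissue-specific (Gini)
   call, targeted by a tissue-specific enhancer, network hub.
6. **Exact clinical statistics.** Two-sided Fisher exact tests
   (minimum-likelihood summation), gene-list overlap tests with fold
   enrichment, and Clopper–Pearson exact binomial confidence intervals.

Because the human embryonic datasets this kind of analysis runs on are
access-restricted, the package ships a first-class synthetic data
generator (`craniodev.synthetic`) that plants known tissue-specific
genes, enhancer placements, coexpression modules with hubs, constraint
structure, and enriched gene lists, together with the ground truth needed
to score every stage.

## Worked example

```python
import craniodev as cd

params = cd.SimParams(seed=4)                      # 10 tissues x 4 samples, 2000 genes
expr, truth = cd.simulate_multitissue_counts(params)
expr = cd.filter_low_expression(expr, "sum", 100)  # drop genes with total count < 100
table = cd.gini_table(expr)                        # gini, assigned_tissue, is_specific
called = cd.call_specific_genes(table, "tissue00")
planted = truth.specific_genes["tissue00"]
print(f"genes kept after filtering: {expr.counts.shape[0]}")
print(f"tissue00 genes called specific: {len(called)}")
print(f"planted tissue00-specific genes recovered: {len(called & planted)}/{len(planted)}")

res = cd.fisher_exact_2x2(3, 1, 1, 3)
print(f"Fisher 2x2 [[3,1],[1,3]]: OR={res.odds_ratio:.1f}, p={res.p_two_sided:.4f}")
ci = cd.clopper_pearson(3, 15)
lo, hi = cd.ci_percent(ci)
print(f"3/15: {cd.proportion_percent(3, 15, 0):.0f}% (95% CI {lo}-{hi}%)")
```

prints

```
genes kept after filtering: 1964
tissue00 genes called specific: 8
planted tissue00-specific genes recovered: 8/10
Fisher 2x2 [[3,1],[1,3]]: OR=9.0, p=0.4857
3/15: 20% (95% CI 4.3-48.1%)
```

Eight of the ten genes planted as tissue00-specific pass the default
`G >= 0.7` call (the two misses fall near the expression filter); no
background gene is called. The Fisher and interval results illustrate the
exact clinical statistics: a 3-vs-1 split in a 2x2 table of eight
observations is far from significant, and a rate of 3/15 carries a wide
exact 95% interval (4.3–48.1%, conservatively rounded outward).

## Command line

Every stage is exposed as a subcommand that reads TSV/BED inputs, writes
TSV outputs, and records a JSON run manifest:

```
craniodev simulate       --outdir sim --seed 4
craniodev gini           --counts sim/counts.tsv --tissues sim/sample_tissue.tsv --outdir gini
craniodev link-enhancers --enhancers sim/enhancers.bed --annotation sim/annotation.tsv \
                         --targets targets.txt --background background.txt --outdir links
craniodev network        --counts sim/timecourse.tsv --outdir net
craniodev enrich         --modules net/modules.tsv --gene-list sim/list_disease.txt \
                         --deciles sim/deciles.tsv --edges sim/edges.tsv --outdir enrich
craniodev prioritize     --gini-genes gini_genes.txt --enhancer-counts links/enhancers_per_gene.tsv \
                         --hubs hubs.txt --deciles sim/deciles.tsv --outdir prio
craniodev stats ci 3 15
```

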