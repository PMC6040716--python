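# coregnet

Integrative TF–miRNA co-regulatory network analysis for multi-group
microarray designs, built around the question: *which genes, transcription
factors and miRNAs change specifically in a diseased cell population, and
how do they regulate each other?*  The motivating design is a four-group
bone-marrow experiment — (non-diabetic / diabetic) × (Lin⁺ cells /
Lin⁻VEGF-R2⁺ endothelial progenitor cells) — where the Lin⁺ fraction serves
as an internal reference, so that expression changes specific to diabetic
EPCs can be separated from general diabetes or cell-type effects.

The package is aimed at systems-biology practitioners who want the full
chain — differential expression, enrichment, network construction, motif
statistics, ontology validation — as composable, tested library functions
rather than a web service, together with synthetic-data generators that
plant known ground truth through every stage.

## What it computes

**Consensus differential expression.** Each of the six pairwise group
comparisons is tested with three callers, and a gene is accepted when at
least two of the three call it:

* SAM statistic `d_g = (x̄_B − x̄_A) / (s_g + s₀)` with pooled standard
  error `s_g` and fudge factor `s₀` (median of the `s_g` by default), with a
  Tusher-style permutation FDR over group-label permutations;
* moderated t-test: gene variances are shrunk toward an empirical-Bayes
  prior, `s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d)`, with `(d₀, s₀²)` fitted by
  moment matching on log variances and `t̃_g` referred to `d₀ + d` degrees
  of freedom;
* ROC AUC of each gene as a two-group classifier (Mann–Whitney identity),
  called at AUC ≥ 0.9 or ≤ 0.1.

The focal comparison's consensus set is then filtered for **exclusivity**:
genes also called in the internal-reference comparisons (those not
involving the diseased EPC group) are removed.

**miRNA enrichment.** For each miRNA, its associated genes (targets ∪
regulator TFs from the interaction database) are tested against the
exclusive DE set with the exact hypergeometric upper tail
`P(X ≥ k) = Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n)`, Benjamini–Hochberg adjusted,
cutoff q ≤ 0.01.

**Network and hubs.** A disease-specific GRN is built from experimentally
supported typed edges (TF→gene, TF→miRNA, miRNA→gene, miRNA→TF) around the
DE genes and enriched miRNAs plus their first-neighbour regulators/targets.
Hubs are the top 10 % of nodes by total degree, ranked separately for the
pooled TF/gene class and for miRNAs (ties at the boundary included).

**FFL motifs and their null.** All 3-node (TF, miRNA, target) triples are
censused and typed by the TF↔miRNA wiring: TF-FFL, miRNA-FFL, composite-FFL
(both edges; never double-counted) and co-regulation (no TF–miRNA edge).
Each motif type's count is compared against `Nr = 100` degree-preserving
edge-swap randomizations (per-class, in/out degrees preserved exactly);
the empirical p-value is `p = Nh/Nr`, where `Nh` is the number of random
networks containing at least as many instances, and types with `p < 0.05`
are significant.

**GO semantic validation.** The co-regulated genes of each examined motif
are scored pairwise with Wang's graph-based term similarity combined by
best-match averaging; the observed score distribution is compared against
100 permutations of equally many random annotated genes with a one-sided
two-sample Kolmogorov–Smirnov test (`D = sup_x [F_null(x) − F_obs(x)]`).

## Worked example

Everything runs end-to-end on synthetic data with planted truth:

```python
from coregnet import simulate_study, run_study, PipelineParams

bundle = simulate_study(seed=1)          # expression + interactions + GO
result = run_study(
    bundle.expression, bundle.design, bundle.db, bundle.dag,
    bundle.annotations, params=PipelineParams(seed=1),
)
```

which, scored against `bundle.truth`, prints:

```text
exclusive DE genes:   83 called, sensitivity 0.988, FDP 0.048
enriched miRNAs:      ['mir-001', 'mir-002', 'mir-003', 'mir-004', 'mir-005']
hubs:                 19 TF/gene, 1 miRNA (mir-001)
TF-FFL          count  12   p = Nh/Nr = 0/100 = 0.00
miRNA-FFL       count   6   p = Nh/Nr = 0/100 = 0.00
composite-FFL   count   4   p = Nh/Nr = 0/100 = 0.00
GO homogeneity (pooled): D = 0.538, p = 5.68e-155
```

Reading this: of the 80 genes planted to shift only in the diabetic-EPC
group, 79 were recovered and 4 of the 83 calls were false; exactly the five
miRNAs planted to target DE genes were enriched; the planted high-degree
regulators surface as hubs; every planted feed-forward-loop type occurs more
often than in any of its 100 degree-matched randomizations; and genes
co-regulated by the planted motif pairs are far more functionally similar
than random annotated genes.

With `outdir=` set, `run_study` writes every stage table (per-comparison DE
TSVs, enrichment, GRN node table plus SIF/GraphML for Cytoscape, motif
census and significance, semantic-similarity CDFs) and a `manifest.json`
of parameters, seeds and stage counts.

The same stages are exposed on the command line:

```bash
coregnet simulate expression --seed 3 --outdir sim
coregnet normalize --in sim/expression.tsv --scale log2 --out norm.tsv
coregnet de --in norm.tsv --design sim/design.tsv --out de_out
coregnet run --config pipeline.yaml        # full pipeline from a YAML config
```

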