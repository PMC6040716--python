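# Methods

This note records the statistical models, the numerical choices, and the
reasoning behind the design decisions in `coregnet`, in the order the
pipeline runs them.

## Study design and preprocessing

The analysis assumes a two-factor, four-group design — disease status
(non-diabetic vs diabetic) crossed with cell population (Lin⁺ reference
cells vs Lin⁻VEGF-R2⁺ endothelial progenitor cells, EPCs) — with all six
pairwise comparisons enumerated in a fixed order (`comp1` ND-Lin⁺ vs
D-Lin⁺, `comp2` ND-Lin⁺ vs ND-EPC, `comp3` D-Lin⁺ vs D-EPC, `comp4` ND-EPC
vs D-EPC, `comp5` ND-Lin⁺ vs D-EPC, `comp6` D-Lin⁺ vs ND-EPC).  The focal
contrast is `comp4`.  Log fold changes are case minus reference, so
positive means up in the diabetic group of that comparison.

Preprocessing is deliberately minimal: constant-offset background
subtraction with a positive floor (default offset 0, floor 1.0 intensity
units — the floor guarantees a defined logarithm and the choice does not
touch any downstream logic), log2 transformation, quantile normalization,
and probe-to-gene collapse by the arithmetic mean.  Normalization is
applied jointly across all samples.  Missing values are rejected rather
than imputed, because no imputation rule is part of the analysis being
modelled.

Quantile normalization uses the average-ties convention: tied values
within a column receive the mean of the rank-means their positions span.
A consequence worth stating precisely is that the textbook invariants
("all columns share one sorted vector", idempotence) hold exactly only for
tie-free columns; ties are replaced by span means, which is the standard
behaviour of the widely used implementations.  Continuous microarray
intensities are tie-free almost surely, and the tests assert the
invariants on that case while pinning the tie behaviour separately.

## Differential expression

Three callers per comparison, on the log2 scale:

* **SAM.**  `d_g = (x̄_B − x̄_A)/(s_g + s₀)` with `s_g` the pooled standard
  error of the mean difference.  `s₀` defaults to the median of the
  `{s_g}` — a deliberate simplification of the original
  coefficient-of-variation search, exposed as a percentile parameter.  The
  permutation FDR orders the observed statistics, compares them rank-wise
  with the mean permuted order statistics `d̄_(i)`, and calls rank `i` when
  `|d_(i) − d̄_(i)| > Δ`.  When the number of distinct group labelings is
  below the requested permutation count the labelings are enumerated
  exhaustively.  The false-call estimate is the median, over permutations,
  of permuted statistics beyond the calling thresholds, with π₀ = 1
  (conservative).  Δ is chosen as the smallest grid value achieving the
  target FDR (default 0.05); per-gene q-values are the smallest FDR at
  which a gene is called, forced monotone in |d|.
* **Moderated t.**  The hierarchical model is a scaled inverse-chi-square
  prior on gene variances, `σ²_g = s₀²·d₀/χ²_{d₀}`; the marginal
  distribution of log sample variances then has closed-form mean and
  variance in digamma/trigamma functions, and `(d₀, s₀²)` are recovered by
  moment matching (trigamma inverted by Newton iteration).  If the
  observed spread of log variances does not exceed its sampling
  expectation, `d₀ = ∞` and all variances collapse to the prior.  With
  `d₀ = 0` the statistic reduces to the ordinary pooled t exactly, which
  the tests assert to 1e-9.  Calls are BH-adjusted p ≤ 0.05.
* **AUC.**  Per-gene ROC AUC via the Mann–Whitney rank identity with ties
  counted ½; called at AUC ≥ 0.9 or ≤ 0.1.  A p-value variant is not the
  default: the fixed cutoff keeps this caller scale-free and independent
  of the other two.

**Consensus** is a plain 2-of-3 vote on gene identity.  Votes are counted
direction-agnostically — a gene called up by one method and down by
another still counts two votes, but such discordance is logged — because
the consensus rule, not per-method directionality, is the methodological
point.

## Exclusivity

The biological question is: which focal-comparison genes are *not*
explained by general diabetes effects or cell-type effects visible in the
reference populations?  `exclusive_de` is pure set algebra — the focal
consensus set minus the union of a stated list of other comparisons'
consensus sets.

Which comparisons to subtract is a genuine design decision, and the
geometry of the design forces a position.  For mean-shift expression
patterns the six pairwise contrasts are linearly dependent: if a gene's
focal difference |μ_c − μ_d| is large enough to call, the triangle
inequality forces a difference at least half as large in some other
comparison sharing a group with the focal pair, so *no* gene can be
exclusively callable in one of six pairwise comparisons under consistent
callers.  Subtracting all five other comparisons would therefore empty the
exclusive set by construction whenever the callers are well behaved.  The
pipeline instead subtracts the comparisons that do not contain the
diseased focal group (`comp1`, `comp2`, `comp6` for focal `comp4`) — these
are precisely the internal-reference contrasts: a change seen among
reference populations is, by the design's own logic, not specific to
diseased EPCs.  The literal all-others subtraction remains available as
`exclusivity="all"`.

## Enrichment statistics

All set tests are exact hypergeometric upper tails, inclusive
(`P(X ≥ k)`), with annotation sets intersected with the stated universe
before testing.  The universe matters and is logged: the default for
miRNA enrichment is all gene/TF nodes of the interaction database, and for
DE-related overlap tests all genes of the (post-collapse) expression
matrix — both overridable, because p-values are only meaningful relative
to a declared universe.  miRNA association sets are target genes united
with regulator TFs (a separate-tests mode exists for the two components).
miRNA enrichment uses BH-adjusted q ≤ 0.01; generic over-representation
analysis uses raw p ≤ 0.05 with terms overlapping the query in fewer than
2 ids skipped, and reports the BH column alongside.

## Network, hubs, motifs

The interaction database is a typed edge table (TF→gene, TF→miRNA,
miRNA→gene, miRNA→TF; a TF is a gene with outgoing regulatory edges, and a
node acting anywhere as TF is classed TF).  Only experimentally supported
edges pass the default filter; duplicates collapse with provenance merged.
The GRN is seeded with the exclusive DE genes and enriched miRNAs;
`expanded` scope (default) adds every database edge touching a seed, which
brings in first-neighbour regulators and targets flagged as such, while
`core` keeps only seed-to-seed edges.  Isolated seeds are retained and
logged.

Hubs are the top `ceil(0.10 × class size)` nodes by total degree, computed
separately for the pooled TF/gene class and for miRNAs; boundary ties are
included (deterministic and auditable — no silent arbitrary drop).  Total
degree is used; in-/out-degree ranking is configurable.

Motif enumeration emits each (TF, miRNA, target) triple exactly once, with
composite-FFL taking precedence when both TF→miRNA and miRNA→TF are
present, so one-way FFL counts never double-count composite wiring.
Co-regulation triples (no TF–miRNA edge) are censused as context but
excluded from significance testing by default.

The null model randomizes each edge class independently by accepted
double-edge swaps (10 × |class| accepted swaps by default; swaps creating
self-loops or duplicate edges are rejected; classes with fewer than two
edges stay fixed), preserving every node's in- and out-degree within every
class exactly.  Type significance is `p = Nh/Nr` with `Nr = 100`: the
fraction of randomized networks containing at least as many instances of
the type.  This estimator can return exactly 0; an add-one corrected
`(Nh+1)/(Nr+1)` is available by flag with the raw value always reported,
because the raw ratio is the quantity the procedure defines.  A
calibration property the tests verify: on networks drawn from the
randomization null itself (after a burn-in randomization, so the draw and
its ensemble are exchangeable), each type is flagged in ≈ 5 % of 200
repetitions within a 99 % binomial band — this holds when type counts are
dispersed; heavy count ties make the inclusive `≥` conservative, which is
the safe direction.

## Semantic validation

Wang's graph-based term similarity: each term contributes S-values over
its ancestor closure (1 for itself, multiplied by an edge weight per hop,
maximized over paths; weights 0.8 for `is_a`, 0.6 for `part_of`), and
`sim(A,B) = Σ_{t∈T_A∩T_B}(S_A(t)+S_B(t)) / (SV(A)+SV(B))`.  It is 1 iff
the terms coincide and needs no information-content corpus, which is why
it is the default; Resnik-style IC measures would require annotation
frequencies the pipeline does not assume.  Gene pairs combine term scores
by best-match average; genes without usable annotations are skipped with a
log message rather than scored 0, which would fabricate dissimilarity.

Each examined motif contributes all pairwise scores of its co-regulated
genes (genes targeted by the motif's TF or miRNA inside the GRN).  The
null resamples, 100 times, the same number of annotated genes uniformly
from the annotated universe and pools all their pairwise scores; the
per-motif count (not a pooled count) is resampled, matching the
per-motif framing of the validation question.  The one-sided two-sample
KS statistic `D = sup_x (F_null − F_obs)` tests whether observed scores
are stochastically larger; the p-value is the one-sided asymptotic
`exp(−2D²mn/(m+n))`, which the tests show is calibrated (flag rate
0.046 at α = 0.05 over 500 null repetitions with n = 200 per sample) and
agrees with an independent implementation.  Per-motif results and a pooled
curve over all examined motifs are both reported, with the empirical CDF
table exported for plotting.

## Synthetic data: what it emulates, and what it does not

`simulate_expression` draws gene baselines from N(8, 1) log2 units and
adds i.i.d. Gaussian noise σ = 0.5 (Student-t with 5 df behind a flag),
9 samples per group (36 arrays).  Planted structure: 80 exclusive genes
shifted by ±2.0 log2 units in the diabetic-EPC group only, and 120 shared
genes split between a diabetes-general pattern (shifted in both diabetic
groups) and a control-EPC pattern (shifted in non-diabetic EPCs only).
Both shared patterns are differentially expressed in the focal comparison
*and* in reference comparisons, so the exclusivity filter is exercised
non-trivially rather than vacuously.  The effect size and noise level are
chosen so the planted contrast is strong (per-gene t ≈ 8 at these group
sizes): the recovery tests measure the pipeline's logic — consensus,
exclusivity, seeding — not borderline detection power.

`simulate_interaction_db` draws background edges per class at a stated
density, then plants FFL triples with exactly the edges their type
requires (regulator pairs chosen round-robin so planted degree spreads
evenly, and pair wiring kept type-consistent), then gives hub nodes enough
gene targets to exceed the maximum non-hub degree of their class by the
stated multiplier (≥3×), verifying the gap and refusing configurations
that cannot guarantee it.  The default configuration is sized so that
`ceil(0.10 × class size)` equals the planted hub count per class (20
TF/gene nodes → 2 TF hubs; 10 miRNAs → 1 miRNA hub), making exact recovery
a well-posed check; FFL planting is therefore opt-in there.

`simulate_go` builds a complete b-ary `is_a` tree (default depth 4,
branching 3 → 121 terms, one namespace) and annotates cluster genes only
with leaves under one depth-2 anchor, background genes uniformly over all
leaves — functional homogeneity with a sharp planted boundary.

`simulate_study` wires the three onto one gene universe: hub TFs and
planted enriched miRNAs target the exclusive-DE genes, background miRNAs
avoid them, planted FFL regulator pairs share several DE targets, and the
co-regulated gene sets of the planted TF-FFL pairs become the ontology
clusters, so every downstream stage has scoreable truth.

What the generators deliberately do **not** emulate: bead-level array
artifacts, batch effects, probe cross-hybridization, correlated noise
between genes, realistic scale-free degree distributions, incomplete or
biased interaction databases, multi-namespace ontologies with partial
annotation depth.  Passing the recovery tests therefore demonstrates that
the pipeline's statistics and set logic do what they claim under their own
model assumptions — it does not certify performance on real arrays, where
normalization residuals, annotation bias and database noise dominate.

## Numerical and implementation choices

* Hypergeometric tails via `scipy.stats.hypergeom.sf(k−1, …)` (exact,
  stable to N ≈ 10⁵); BH via statsmodels, permutation-invariant by
  construction.
* Trigamma inversion: Newton iteration from `y = 0.5 + 1/x`, with the
  asymptotic branches `1/x` (small x) and `x^{-1/2}` (large x); degenerate
  non-positive moment estimates map to `d₀ = ∞` (full shrinkage).
* Edge-swap randomization caps attempts at 100 × the requested accepted
  swaps and logs incomplete mixing; random index pairs are drawn in
  batches for speed.
* Determinism: every stochastic routine takes a seed; composite drivers
  derive child seeds via `SeedSequence`, and reruns with equal seeds
  produce byte-identical tables.  Stage results are cached under the
  output directory keyed by an input checksum, so re-running a completed
  stage with unchanged inputs is a no-op.
* Ordering is made deterministic everywhere results are emitted (sorted
  nodes, sorted terms, stable sorts on ties) so outputs are reproducible
  across runs and platforms.
* Test problem sizes: the oracle-equivalence layer uses networks of ≤ 40
  nodes (200 replicates) and exhaustive urn enumeration to N = 12; the
  recovery layer runs the full 1000-gene, 36-sample study once at
  defaults; the null-calibration layer uses 200 repetitions of Nr = 100
  randomizations on a ~300-edge network and 500 KS repetitions at n = 200.
  These sizes were chosen to make the checks sharp while keeping the whole
  suite comfortably interactive.

## Known limitations

* The SAM variant is the symmetric rank-difference rule with a median-based
  fudge factor, not a reimplementation of any specific package's exact
  output; its q-values are conservative (π₀ = 1).
* `p = Nh/Nr` is granular at 1/Nr and can be exactly 0; with heavily tied
  motif counts the inclusive tie rule makes it conservative.
* The exclusivity filter's default reference set encodes the internal-
  reference design logic; analyses with different designs must choose the
  subtracted comparisons explicitly.
* Wang similarity treats the ontology as is; obsolete terms, cross-
  namespace annotations and regulation-type edges are out of scope.
* The enrichment universe defaults are sensible but consequential;
  changing them changes p-values, which is why they are logged.
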