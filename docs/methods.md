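# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, the design decisions that were genuinely
open, and what the synthetic-data experiments do and do not demonstrate.

## Shared-miRNA significance

A lncRNA–mRNA pair is a ceRNA candidate when the two transcripts share more
miRNA partners than chance predicts. With a universe of N miRNAs, per-gene
set sizes K and M and overlap x, the null overlap is Hypergeom(N, K, M).
Two upper tails are implemented because the ceRNA literature prints both:

* `at_least` — P(X ≥ x), the conventional enrichment p-value (default);
* `greater_than` — P(X > x) = 1 − Σ_{t≤x} P(X = t), the literal
  complement-of-CDF form. It excludes the observed overlap and returns
  exactly 0 whenever x = min(K, M), i.e. whenever one set contains the
  other — a degenerate answer for a p-value, which is why it is not the
  default.

Both are computed through the log-space survival function of
`scipy.stats.hypergeom`; no normal approximation is used, and the test
suite pins both tails to exact integer-combinatoric enumeration (1e−12)
for every (N, K, M, x) with N ≤ 12.

Conventions the data do not decide, fixed as defaults:

* **Universe N** is the union of miRNAs over both gene classes after
  evidence filtering. Whether a resource-wide miRNA count or only
  interacting miRNAs should define N is a modelling choice; the union is
  recorded in the run manifest and a user-supplied universe can replace it.
* **Evidence filter**: miRNA–lncRNA interactions are restricted to
  `supported` records (AGO-CLIP-style validation encoded upstream as an
  evidence label), miRNA–mRNA interactions are accepted with either label,
  since curated mRNA-target databases are already experimental. Default
  `classes_to_filter = {lncRNA}`, configurable.
* **FDR family**: Benjamini–Hochberg over all eligible pairs jointly (one
  family), not per-lncRNA. Pairs with x = 0 are excluded by default
  (p = 1; they cannot pass FDR < 0.01) but can be included with
  `min_shared=0`.
* Genes whose miRNA set is empty after filtering are excluded from pair
  testing: K = 0 or M = 0 makes the test degenerate.

## Co-expression filter

Candidates become network edges when Pearson r (exact two-sided t
reference, n − 2 df) passes BH FDR < 0.01 *and* r > 0. The positivity
requirement is a modelling statement — competition for a shared miRNA pool
implies positive co-expression — and can be switched off
(`require_positive=False`). Edges with r > 0.5 (strict) additionally form
the high-competition sub-network; by construction its edge set nests inside
the full network's. The FDR family is the candidate list only, not all
possible pairs. A seeded permutation p-value is available for small n.
Missing values use pairwise-complete samples with a floor of 10 shared
observations, below which the pair is flagged undefined and fails both
filters. Inputs are assumed batch-corrected upstream; no batch correction
is implemented (the generator has an off-by-default `batch_offset` hook for
sensitivity experiments).

Quantile normalization maps every sample column onto the mean order-
statistic distribution with average-rank tie handling; log2 transform is
elementwise with a non-negative offset. Both are preprocessing helpers for
array-like inputs; the synthetic generator emits data already on a log2
scale, so the pipeline does not apply them by default.

## Network topology

The network is undirected and bipartite (every edge joins a lncRNA and an
mRNA); correlations are edge annotations, shortest paths are unweighted.
Betweenness is reported in two variants because the two textbook phrasings
are not the same quantity:

* `betweenness` — the Brandes sum Σ_{s≠t≠v} σ_st(v)/σ_st over unordered
  pairs (computed by networkx, unnormalized);
* `betweenness_global` — Σ σ_st(v) divided by the total number of shortest
  paths in the network.

The two weight node pairs differently (the global variant up-weights pairs
with many shortest paths), so their rankings can differ slightly on graphs
with non-unique shortest paths; they coincide exactly on trees. Hub and
bottleneck selection ranks by the Brandes variant. Hubs are the top
⌈0.05·class size⌉ lncRNAs by degree, bottlenecks the same fraction by
betweenness, the reported set is their intersection; ties at the boundary
break by the other metric and then lexicographic id, making selection
deterministic. The ceiling convention reproduces the usual "top 20 of 393"
arithmetic.

Degree distributions are fitted by least squares on (log10 degree,
log10 frequency) over distinct observed degrees — the R²-style reporting
conventional for scale-free claims in this literature — rather than by
maximum-likelihood exponent estimation, which answers a different question.
Fits with fewer than 3 distinct degrees are flagged not fittable.

## Maximal biclique modules

A competing module is a maximal complete bipartite subgraph of the
sub-network. Enumeration is consensus-style: every candidate mRNA set is
closed against the lncRNA neighborhoods (A = all lncRNAs containing the
set, B = intersection of their neighborhoods), seeds are the vertex stars,
and intersections of discovered mRNA sides are re-closed until no new
maximal biclique appears. Correctness is anchored to an exhaustive
subset-enumeration oracle (all random bipartite graphs up to 8+8 nodes in
the suite) rather than to any particular published variant. Default size
minima are 2 lncRNAs × 3 mRNAs — the shape of a five-member synergistic
module — and modules are ranked by total size, then mean edge correlation.
The enumeration is exponential in the worst case and intended for the
sparse sub-network, not the full network.

## Survival modelling

Univariate Cox proportional-hazards fits maximize the Breslow partial
likelihood by Newton–Raphson: convergence when successive log-partial-
likelihoods differ by < 1e−9, at most 50 iterations, step-halving on
overshoot. Breslow tie handling is the classical default of the array-era
tooling this pipeline mirrors; with continuous times it coincides with
Efron's. Wald standard errors give 95% CIs and two-sided p-values. Fits
with |β| > 10 or SE > 100 are flagged unreliable (monotone likelihood:
a perfectly separating covariate drives β to ±∞ with a flat likelihood,
so the Newton iteration "converges" at an arbitrary large value). The
suite cross-checks coefficients, SEs and p-values against lifelines
(untied data) and scikit-survival's Breslow implementation (tied data).

The risk score is the linear form Σᵢ rᵢ·Exp(i) over screened candidates,
with expression used as-is on the log2 scale (not re-standardized — the
score is a literal weighted sum of expression values). The screening
threshold is Wald p < 0.05; if nothing passes, the model falls back to all
candidates with a warning so the (correctly non-significant) stratification
is still reported. The cutoff is the training median; scores exactly equal
to the cutoff are assigned low-risk. Test and external cohorts reuse the
training coefficients and cutoff verbatim — no re-fitting — which is what
makes the held-out p-values honest. Kaplan–Meier curves and the two-group
log-rank test come from lifelines. The train/test split is a seeded random
partition (default 0.5, sizes within 1), with an optional chi-square
comparability report for categorical covariates.

## Guilt by association

A focal lncRNA is profiled through its network neighbors: their expression
submatrix is clustered on both axes with average linkage on 1 − Pearson
distances (the standard for expression heatmaps; constant vectors fall back
to the maximum distance of 2), trees are cut with scipy's maxclust
criterion. Defaults of 4 gene clusters × 3 patient groups suit a
257-neighbor use case but the CLI makes both counts explicit required
arguments to avoid silent assumptions. Gene-set enrichment reuses the same
verified hypergeometric core as the shared-miRNA test (one implementation,
two call sites), with the background universe defaulting to all genes in
the expression matrix and BH FDR across the sets of the collection. GO or
pathway collections are user-supplied GMT files; nothing is downloaded.

## Synthetic cohorts

The generator produces the structure the pipeline assumes, with a known
answer key:

* **Interactions**: each gene draws a miRNA set of uniform size within its
  class range (defaults 8–15 of 150 miRNAs). Planted units — singleton
  pairs or one complete module — share a forced core of
  ⌈shared_fraction · min set size⌉ miRNAs (default 0.8); all other overlap
  is chance.
* **Expression**: Gaussian on the log2 scale around a baseline of 6 (array-
  like intensities); genes of a planted unit load on a shared latent factor
  z ~ N(0,1) as expr = μ + z + noise_sd·√((1−ρ)/ρ)·ε. At the default
  noise_sd = 1 the expected Pearson correlation of unit members is exactly
  ρ = pair_correlation (default 0.9); noise_sd = 0 gives r = 1; unplanted
  genes are independent with matched total variance.
* **Survival**: exponential proportional hazards,
  λᵢ = baseline_hazard·exp(Σⱼ βⱼ z_ij) on gene-wise standardized risk-gene
  expression, so βⱼ is a scale-free per-SD log hazard ratio. Defaults:
  one risk gene at β = 0.7, baseline hazard 0.055 per month (mean survival
  ≈ 18 months), and independent exponential censoring whose rate is solved
  by bisection so the expected censored fraction matches censoring_rate
  (default 0.12, the order of a mature tumour cohort). Default cohort size
  is 422 patients, split 211/211.
* **Determinism**: every stage draws from a generator seeded by
  (config seed, stage index); identical configs give byte-identical
  cohorts, and the pipeline derives the external-cohort and split seeds
  from the global seed by fixed offsets so toggling one stage never shifts
  another's randomness.

What the generator does *not* emulate: heavy-tailed or bimodal expression
marginals, batch structure (hook off by default), miRNA-expression-mediated
dependence between pairs, non-proportional or time-varying hazards, and
informative censoring. Passing tests therefore demonstrate correctness of
the inference machinery under the stated model, not robustness to the
messiness of real array data.

## Calibration and recovery experiments

Null calibration uses cohorts with no planted structure. Correlation
p-values are continuous and checked directly for uniformity (KS < 0.05 at
1,200 pairs, n = 200 samples). Hypergeometric p-values are *discrete*: with
small miRNA sets the p-value support is a coarse staircase (about half of
all null pairs share zero miRNAs and get p = 1), and no discrete test
statistic can look uniform. The calibration run therefore uses a
dense-overlap regime — 1,000 miRNAs, set sizes 200–400, 80×80 genes
(6,400 pairs) — where the support is fine enough that super-uniformity is
the only remaining deviation; the KS statistic then sits well below 0.05.
Log-rank type-I error is estimated from 2,000 two-arm null replicates
(30 + 30 patients, exponential times, no censoring) at α = 0.05.

Planted-structure recovery runs the full pipeline on a 600-patient cohort
with 20 planted pairs including a 2×3 module (sharing 0.8, correlation
0.9) and one risk gene at β = 0.7, checking pair recall at FDR < 0.01,
the module's rank, coefficient recovery within ±0.15, and significant
train / held-out test / external stratification. Problem sizes throughout
the suite (hundreds of genes, ≤ 600 patients, ≤ 12-node oracle graphs) are
chosen so every oracle remains exhaustively enumerable and the whole suite
runs in minutes on a laptop.

## Known limitations

* The hypergeometric test conditions on fixed set sizes and ignores miRNA
  identity, binding strength and expression; conditional or
  partial-correlation ceRNA tests are out of scope.
* Pearson-only co-expression (no rank-based or robust alternatives) is a
  fidelity choice, sensitive to outliers in real data.
* Only univariate Cox screening is provided — no covariate adjustment,
  multivariate selection or proportional-hazards diagnostics.
* Biclique enumeration does not merge overlapping modules or handle
  quasi-bicliques.
* Patient-group survival comparisons in the association stage are pairwise
  log-rank without multiplicity correction.
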