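# Methods

## Pipeline model

`hubdrug` treats a panel of untreated cell lines as a genes × samples
log-scale expression matrix and a long table of (cell line, drug, value)
sensitivity records on one of two scales: a direct scale (activity area,
AA — higher = more sensitive) or an inverse scale (natural-log IC50 —
lower = more sensitive). The analysis has five stages; each is a pure
function of its inputs plus an explicit seed.

### Variance filter

Per-gene SD uses the n−1 (sample) denominator. The threshold is the
linear-interpolation percentile of the full SD distribution, and selection
is *strictly above* the threshold, so ties at the threshold are excluded
and selection counts are deterministic. The default percentile of 99 is a
deliberately stringent cut that keeps only the most variable tail of the
transcriptome; with the synthetic generator's 4× variance boost on planted
module genes, the planted structure survives this cut whenever modules
make up at most the retained fraction of the gene pool.

### Co-expression network

All pairwise Pearson correlations among retained genes form a complete
weighted graph. Degrees are computed on nonnegative transforms of r —
`abs` (|r|, default) or `squared` (r², the variance-explained weighting) —
because signed weights would make the permutation test on degree sums
uninterpretable (positive and negative edges would cancel). Zero-variance
genes are rejected with their ids rather than silently dropped, so gene
order never desynchronizes between tables.

### Permutation hub test

A hub is a node whose weighted degree is improbably large under a null in
which the multiset of off-diagonal edge weights is uniformly reassigned to
the edge slots of the same complete topology. Degree-preserving rewiring
is vacuous on a complete graph, so the test targets exactly what
distinguishes a hub there: the *concentration* of large weights on one
node. Empirical P-values use the add-one estimator
`(1 + #{d_b ≥ d_obs})/(B + 1)` (never zero), ties count toward the
numerator (conservative), and Bonferroni correction multiplies by the
number of tested nodes, capped at 1. Defaults: α = 0.05 and B = 100,000
(B = 2,000 is a practical test-suite preset; the permutation count is a
free parameter).

Two samplers generate the null:

- `matrix` (default): every permutation shuffles the full weight multiset
  and recomputes all degrees (one B×m permutation block multiplied against
  the edge-node incidence matrix).
- `pooled`: under whole-matrix shuffling, a single node's null degree is
  the sum of n−1 weights drawn without replacement from the pooled
  multiset; draws are generated directly that way and shared across nodes
  (all nodes have the same null marginal). This is far cheaper on large
  networks (O(B·n) instead of O(B·m·n)) and is validated against `matrix`
  by a two-sample Kolmogorov–Smirnov test in the suite. Because draws are
  shared, P-values are positively correlated *across nodes* within a run;
  each node's P-value remains a valid estimator, so use `pooled` for
  detection and recovery at scale and `matrix` when the joint behaviour of
  P-values across nodes matters (e.g. calibration studies).

A small-network exact oracle enumerates the null directly: the weights
incident to one node form a uniform without-replacement sample of n−1 of
the m pooled weights, so the exact P-value is the fraction of
(n−1)-subsets whose sum reaches the observed degree.

**Known limitation — a heavy-tailed null on planted-module data.** When
the network contains tightly correlated modules, the pooled weight
multiset is bimodal: a null draw that happens to collect many of the large
within-module weights can reach the observed degree of a true hub. The
tail probability is tiny (~1e-6–1e-5 per draw at the default synthetic
conditions) but not zero. Combined with the Bonferroni threshold, this
matters exactly when `0.05/n_nodes` is within one add-one step of the
estimator floor `1/(B+1)`: at B = 10,000 and 350 nodes a hub is declared
only if *zero* of the 10,000 draws reach its degree, so single tail events
occasionally drop a true hub just past the threshold. Raising B (the
default is 100,000) moves the floor far below the threshold and restores
headroom; the r² transform also sharpens the contrast. The recovery test
in the suite asserts the stringent B = 10,000 setting as-is and therefore
documents this edge rather than hiding it.

### Sensitivity model

Each training row is one cell line–drug experiment: k z-scored hub-gene
expressions followed by a one-hot drug-identity block, with the observed
AA as target. A single pooled linear model is fitted by the penalized
normal equations on centered features, with the intercept unpenalized (so
the infinite-penalty limit returns the target mean) and the residual of
the normal equations checked to 1e-10 relative tolerance. The default
penalty λ = 1e-8 is effectively OLS while remaining solvable under the
strong collinearity expected among co-expressed hubs; drug-indicator
coefficients are penalized like any other coefficient (immaterial at this
λ, but it makes larger-λ sweeps well-defined).

The drug-identity encoding is the minimal structure that lets one pooled
model score any sample against any drug: predictions for a fixed sample
differ between drugs by exactly the difference of their indicator
coefficients. This additivity is also the model's main limitation: true
gene–drug interactions (drug-specific effect vectors) are averaged into a
single shared coefficient vector. The synthetic generator can plant either
regime; tests that require a *noiselessly recoverable* target (e.g.
out-of-fold CI ≥ 0.99 at zero noise) use a shared effect vector across
drugs, because with drug-specific effects the pooled model is misspecified
by construction and tops out well below 1 even at zero noise.

Standardization defaults to `global` (z-scores fitted on the whole matrix
before cross-validation, the historical convention for this analysis);
`per_fold` refits scaling on each training fold and applies it to the held
fold (leakage-safe). On well-powered synthetic data the two differ by less
than 0.01 in out-of-fold CI, which the suite checks. Fold assignment is a
seeded uniform permutation chunked into k near-equal folds; leave-one-out
is the k = n special case.

The lasso comparator mirrors a sparse baseline: outer folds stratified by
drug (within each drug, records are sorted by sensitivity and consecutive
blocks dealt one to each fold, so folds share drug proportions and value
distributions), inner CV selecting the penalty that minimizes held-out
RMSE on a descending log grid from the data-driven maximum. The solver is
scikit-learn's coordinate-descent `Lasso`.

### Evaluation

Kendall tau is the tie-corrected tau-b (identical to tau-a on tie-free
data, which the brute-force oracles exploit). The concordance index is
`(τ+1)/2` for direct orientation and `(1−τ)/2` for inverse orientation;
the inverse form is an algebraic identity with negating the observations,
implemented as a rescaling so tie handling stays symmetric. Approximate
95% intervals map a symmetric interval on `atanh(τ)` with the
Fieller–Hartley–Pearson variance `0.437/(n−2)` through the orientation
rescaling; simulation (Gaussian copula, τ = 0.4, n = 200) puts empirical
coverage at 95% ± 5%. Exact ±1 tau yields a degenerate interval clipped to
[0, 1].

Extreme-responder AUC z-scores observed values within each drug, labels
sensitive (> 0.8) and resistant (< −0.8), drops intermediates, and
computes the Mann–Whitney probability that a random sensitive sample
outscores a random resistant one (cross-class ties count 0.5). Per-gene
sensitivity correlations replicate each cell line's expression across its
drug records before correlating, and the hub vs non-hub comparison is a
pooled-variance two-tailed t-test on those per-gene values.

## Synthetic generator

Each module m has one standard-normal latent factor per sample; gene i in
module m is `loading_i · f_m + ε`, ε ~ N(0, noise_sd²), with the first
gene carrying `hub_loading` and the rest `member_loading`. All module
genes are then scaled by `hub_variance_scale` so the planted structure
passes a stringent variance filter; background genes are pure noise.
Factors are independent across modules, giving a clean null for
false-positive accounting. Sensitivity is
`AA = μ_d + Σ_j β_dj · z_cj + ε` over the per-gene standardized planted
hub expressions, and the paired inverse-scale table is
`α − γ·AA + ε_inv` with γ > 0.

Defaults describe the reference study conditions: 350 genes (5 modules of
10 in 300 background), 500 cell lines, hub/member loadings 0.95/0.7,
residual SD 0.3, variance boost 4×, 24 drugs with intercepts spanning
0.5–4 AA units and moderate effects (|β| ≤ 0.6) drawn once from the root
seed and stored in the config, AA noise SD 0.5, inverse map
(α = 2, γ = 1, σ = 0.3). All draws flow from per-operation sub-streams of
the single config seed, so outputs are bit-reproducible.

What the generator does *not* emulate: tissue-site or batch structure,
probe-level microarray noise, count-based RNA-Seq distributions, missing
sensitivity records, or gene–gene correlation beyond the one-factor
module structure. Passing recovery tests therefore demonstrate internal
consistency of the pipeline under a known linear ground truth, not
performance on real panels.

## Numerical choices

- Percentile: linear interpolation between order statistics; strict
  selection above the threshold.
- Degree ties in the permutation test: compared with a relative slack of
  1e-9 so re-summing an identical weight multiset in a different floating
  point order still counts as a tie (this keeps the exchangeable-null
  case at P = 1 exactly).
- Ridge: symmetric solve of the penalized normal equations; singular
  systems at λ = 0 raise with advice to use a positive penalty.
- Serialization: floats as decimal text with 17 significant digits and
  round-trip parsing on read, so write → read is lossless and the CLI
  chain is byte-deterministic under a fixed config and seed.
- Problem sizes in the test suite are chosen for fast, stable statistics
  at desk scale: calibration uses 50 replicates of 50-node networks at
  B = 2,000; recovery uses the default study-scale generator with the
  `pooled` null sampler; closed-form correlation checks use n = 5,000.
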