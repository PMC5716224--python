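# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the places where the design was genuinely open.

## Data model

The pipeline's currency is a dense genes × samples matrix with unique,
ordered identifiers and an explicit `value_space` tag (`counts`, `raw`,
`log`, `normalized`). Stages never re-transform data implicitly; the tag
lets consumers assert they receive the intended scale (the dispersion
estimator, for instance, refuses log-scale input). Merging multiple
plates takes the **intersection** of gene sets: a union would fabricate
zeros in plates that simply did not measure a gene, and those fabricated
zeros would masquerade as batch effects downstream. Log transformation is
log2(x + 1); base 2 with pseudocount 1 is the dominant convention in this
field and makes a unit difference an exact two-fold change.

Matrix files are written with `%.17g` so float64 values round-trip
bit-exactly through CSV (the reader uses a correctly rounded parser).

## Batch correction

*Median alignment* is a purely multiplicative correction: per-sample
medians are computed over strictly positive entries only, because
single-cell matrices are zero-inflated and a literal column median of 0
would make the geometric means undefined. The per-batch factor
G/batchMean_b (G the global geometric mean of medians) makes the
correction idempotent, scale-equivariant, and rank-preserving within each
sample — properties the test suite asserts. It is value-space-agnostic:
it rescales whatever scale it is handed and never log-transforms
internally.

*Empirical-Bayes adjustment* targets additive log-scale batch effects.
Per gene the data are standardized by the size-weighted grand mean and
pooled variance; per gene-and-batch location (γ) and scale (δ²) effects
are estimated and shrunk toward a normal prior on γ and an inverse-gamma
prior on δ², with hyperparameters from cross-gene method of moments and
the standard coupled posterior-mean iteration (converged when the largest
δ² change is below 1e-6, capped at 100 iterations). Only the parametric,
no-covariate variant is implemented. Zero-pooled-variance genes are
passed through with a warning — shrinking them would divide by zero for
no benefit. An independent implementation of the same adjuster (scanpy's)
agrees to ~4e-3 absolute on a Gaussian fixture; the residual comes from
minor standardization details and is covered by a tolerance in the test.

## Outlier detection

Cells are scored by the Euclidean norm of their expression vector after
per-gene standardization (zero-SD genes dropped first — they carry no
signal and would divide by zero). The z rule is **two-sided** (|z| >
threshold, default 2). The design was open between one- and two-sided; the
generator settled it: a cell whose library is scaled down 5-fold has its
whole profile compressed toward the zero-inflated floor, so its
standardized norm is unusually *small* (z ≈ −3.3 on typical simulations),
while doublet-like or contaminated cells inflate the norm. A high-tail
rule would systematically miss degraded libraries — the most common real
failure mode — so both tails are flagged. The fixed-count mode (top-n by
norm) breaks ties by sample order and is deterministic.

The norm depends on the scale of the input (raw vs log); the caller
passes the intended matrix and the report records the value space used.

## Gene filtering

The dispersion φ is the method-of-moments estimate from Var = μ + φμ²,
clamped at 0 where the sample variance falls below the mean
(under-dispersion has no NB interpretation) and undefined for zero-mean
genes, which can never be kept. The mean–dispersion trend is an ordinary
least-squares fit of φ = a₀ + a₁/μ over genes with positive φ — OLS
rather than a gamma GLM because it is deterministic, closed-form, and
exact on noiseless data, which the tests exploit; fitted values are
floored at 1e-6 so the keep ratio is always defined. The keep rule is the
conjunction μ > mean_threshold and φ > ratio·φ̂(μ), monotone in both
thresholds.

## Normalization

Quantile normalization uses the classic rank-mean construction. The tie
rule — a tie group receives the mean of the reference values across the
group's rank span — is the common convention; note that columns with
ties therefore do not reproduce the reference multiset exactly (only
tie-free columns do), which is inherent to any averaging tie rule.
Geometric-mean alignment and size factors use geometric means over
strictly positive entries. Size factors follow median-of-ratios against a
per-gene geometric-mean reference restricted to genes positive in every
sample, then are rescaled to geometric mean 1 so normalization
redistributes depth without changing the overall scale. On heavily
zero-inflated matrices no gene may be positive everywhere; size factors
are then undefined and the operation refuses rather than guesses.
Precision-weight normalization for external linear-model engines (voom)
is deliberately not provided; the CLI points users to the three native
methods.

## Embedding and clustering

The correlation distance 1 − Pearson(Sᵢ, Sⱼ) is computed between sample
columns, symmetrized, clipped to [0, 2]; constant columns are an error
naming the sample. t-SNE consumes this matrix as a precomputed metric and
is deterministic given its seed; the perplexity must stay below (m−1)/3,
and the helper default is 0.75·(m−1)/3 capped at the conventional 30.
PCA treats samples as observations with per-gene centering and fixes
signs by making the largest-magnitude loading of each component positive.
k-means uses 10 restarts, best by within-SS; hierarchical clustering is
complete-linkage; NMF assigns each sample to the argmax over the k rows
of its W column (ties to the lowest component index). All labels are
renumbered 1..k by first occurrence. The inner solvers are scikit-learn's
and scipy's; what this package pins is the contracts: seed-determinism,
precomputed-distance input, membership and tie rules.

### Elbow selection of k

For each k in 2..10 the clusterer runs and EV(k) = 1 − withinSS/totalSS
is computed **on the same coordinates the clusterer saw** (t-SNE
coordinates for the *_tsne methods, the expression columns otherwise) —
EV is defined once and reused for every method. The elbow model is a
rise-then-plateau curve anchored at the origin and continuous at the
breakpoint, f(k) = β·min(k, m) with β ≥ 0; this is the simplest model
consistent with "linear from 0 to m, constant afterwards" and reduces the
fit to the closed form β̂ = Σ EV·min(k,m) / Σ min(k,m)². The breakpoint m
ranges over 1..10; the best-R² m (ties to the smallest) is the elbow, and
the recommended k is clamped into the clustering range [2, 10]. A flat EV
curve has no elbow and returns the smallest k. An exhaustive grid-search
oracle over β confirms the closed form on random curves.

## Differential expression

The built-in statistic is labelled **welch-z** everywhere: a Welch
t-statistic on log expression mapped through the two-sided p-value to a
standard-normal quantile with the t's sign. This puts genes with very
different within-group variances on one N(0,1) scale, which is what the
downstream enrichment walk consumes. Degenerate genes: zero variance in
both groups with equal means score 0; with unequal means the call is
infinitely confident and is capped at ±38 (the quantile's float64
saturation point). Rankings sort descending with ties broken by gene
order. Pairwise DE runs every unordered cluster pair; pairs with a
cluster below 2 samples are skipped with a warning; the worker count
parallelizes over pairs and never changes results.

## GSEA

The enrichment score is the classic weighted running sum (weight 1 by
default): hits advance by |stat|^w/N_R, misses retreat by 1/(N−N_hits),
and the ES is the signed extreme of largest magnitude. A set whose
statistics are all exactly zero falls back to equal hit increments. The
implementation evaluates only the running-sum values adjacent to hits
(the only possible extremes), so permutation nulls are vectorized; a
brute-force full-walk oracle confirms it to 1e-12.

The null is **gene-label** permutation: random same-size gene subsets of
the ranking, shared across sets of equal size. This matches fast-GSEA
practice and needs no expression matrix at enrichment time. The p-value
is the +1-corrected two-sided tail probability of |ES| under that null,
p = (1 + #{|ES_null| ≥ |ES_obs|})/(1 + n_perm). The two-sided-magnitude
form was chosen over a sign-side count against the full null because it
is a pure rank statistic: exactly uniform when the ranking carries no
signal (which the calibration test checks by KS distance) and bounded
below by 1/(n_perm+1), which a genuinely enriched set attains. Direction
is read from the signed ES. BH adjustment runs across the retained sets
(size filter 5..500 on the intersection with the ranking, duplicates
within a GMT set deduplicated).

## Synthetic data

The generator emulates the generative skeleton of standard single-cell
simulators, not any particular tool: gene base means LogNormal(0.5, 1);
round-robin cluster membership; per cluster a disjoint 10% block of genes
up-regulated by an 8-fold effect; library factors LogNormal(0, 0.2); NB
counts with φ = 0.5 (Poisson at φ = 0); dropout applied after the count
draw, zeroing entries with probability logistic(slope·(midpoint −
log(mean+1))), midpoint 1, slope 1. Defaults are pinned once as
plausible droplet-experiment values (about 60% zeros, clearly separable
populations) and the documented experiments use them unchanged: 200–300
cells for clustering studies, 60 cells for batch experiments, 100 cells
with one injected outlier for QC, 2000 cells where estimator convergence
is measured. Batch injection multiplies a random half of the columns by
3; outlier injection divides cells by 5 (low-expression failures).

What it does **not** model: gene–gene correlation beyond cluster
structure, mean-dependent dispersion, doublets, ambient RNA, or batch
effects beyond a global scale factor. Tests passing on this generator
therefore demonstrate algorithmic correctness and calibration under the
stated model, not robustness to every artifact of real droplet data.

## Pipeline

Stages execute in the fixed dependency order merge → batch_correct →
outlier_removal → normalize → gene_filter → log_transform → cluster → de
→ gsea; any optional stage can be skipped (explicitly or by omission) and
its input passes through. Config validation rejects order violations and
missing dependencies before anything runs. All randomness flows from the
single config seed; the manifest records parameters and SHA-256 checksums
of every artifact, and stage-by-stage CLI execution with the same
parameters reproduces the pipeline's bytes.

## Known limitations

- The empirical-Bayes adjuster has no covariate support, reference-batch
  mode, or non-parametric prior.
- The welch-z statistic is a pragmatic built-in, not a replacement for
  count-model DE engines; outputs are labelled so results are never
  mistaken for them.
- EV-based elbow selection inherits EV's bias toward larger k on
  high-dimensional raw coordinates; it is sharpest on 2-D embeddings.
- Size factors require at least one gene observed in every cell.
- Dense matrices only; memory scales as genes × cells × 8 bytes.
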