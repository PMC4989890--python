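# Methods

`irnet` infers association networks between two omics layers measured on the
same samples — in the motivating use case, gene-level DNA methylation
(features, X, n × J) and mRNA expression (traits, Y, n × K). Rather than
testing marginal correlations, it regresses all traits on all features with
four penalized multi-output models, converts each coefficient matrix into
similarity networks over features and over traits, fuses the per-method
networks into one consensus network, and keeps only edges that survive a
permutation-derived weight threshold.

## Model and estimators

The generative model is linear per trait: `y_k = b_0k + X b_k + eps`,
`eps ~ N(0, sigma^2)`. Both X and Y are standardized column-wise (mean 0,
SD 1 with the n−1 denominator) before fitting; intercepts are recovered by
centering and are never penalized.

The four estimators of B = {b_jk} and their objectives, implemented exactly
as written (note the deliberately different loss scalings — reduction
identities between the methods rescale the penalty accordingly):

1. **Lasso**, per trait: `||y − Xb||² + λ·||b||₁`. Cyclic coordinate descent
   on the Gram matrix with entrywise soft-thresholding. Exact zeros come
   from the threshold operator itself, never from post-hoc rounding.
2. **Graph-guided fused lasso (GFLasso)**, joint over traits:
   `Σ_k ||y_k − Xb_k||² + λ||B||₁ + γ Σ_(m,l)∈E f(r_ml) Σ_j |b_jm −
   sign(r_ml) b_jl|`. The trait graph E connects pairs with
   |Pearson r| ≥ 0.7 (threshold configurable); `f(r) = |r|`, with the sign
   carried into the fusion term so anti-correlated traits are fused with
   flipped sign. The non-separable fusion term is smoothed (Nesterov
   smoothing, target μ = 1e-4 approached by ×100/×10 continuation) and
   minimized by monotone accelerated proximal gradient (MFISTA), with the
   L1 term handled by its prox. Monotone acceptance is evaluated on the
   *unsmoothed* objective, so the recorded trajectory is non-increasing by
   construction. When γ = 0 or E is empty the problem is the lasso and is
   delegated to coordinate descent, making the reduction identity exact.
3. **Sparse group lasso (SGL)**, per trait:
   `(1/2n)||y − Xb||² + (1−α)λ Σ_l √p_l ||b^(l)||₂ + αλ||b||₁` over a
   partition of features into groups (default: 20 groups from Ward
   clustering). Block coordinate descent over groups: each block first
   checks the group-zero condition, otherwise runs inner proximal steps
   whose operator — entrywise then groupwise soft-thresholding — is the
   exact prox of the combined penalty on a non-overlapping group. Default
   mixing α = 0.1.
4. **Structured input–output lasso (SIOL)**, joint:
   `½||Y − XB||²_F + λ₁||B||₁ + λ₂ Σ_k Σ_g ||b_k^g||₂ + λ₃ Σ_j Σ_h
   ||b_h^j||₂`, with feature groups G and trait groups H (both from Ward
   clustering, 20 each). The L1 + column-group + row-group penalties
   overlap, so their joint prox has no closed form; it is evaluated by a
   Dykstra-like cyclic scheme over the three simple proxes (exact in one
   pass when groups are singletons), inside MFISTA. Default secondary
   penalties are tied to λ₁ at ratios 3:2, mirroring the reference ratio
   0.1 : 0.3 : 0.2.

Convergence for all solvers: relative objective change < 1e-7 (or the
caller's tolerance) or 10,000 iterations; non-convergence is flagged in the
diagnostics, not fatal. Objective trajectories are non-increasing (enforced
by monotone acceptance where acceleration could overshoot).

### Penalty selection

`select_lambda_cv` does K-fold cross-validation (random fold assignment,
mandatory seed) over a geometric grid from the smallest all-zero penalty
λ_max down to `lambda_min_fraction · λ_max`, warm-starting down the path.
Defaults: fraction 0.01 for lasso and SIOL, 0.8 for SGL (the reference
analysis's choice). GFLasso instead explores {½, 1, 2}× around a heuristic
initial λ — the median nonzero |β| of a preliminary lasso fit times the
trait count — crossed with γ ∈ {½, 1, 2}.

**Benchmark protocol.** The synthetic benchmark (`irnet.benchmark`) tunes
*all four* methods over the full path (fraction 0.01). On the strong-signal
synthetic scenario the SGL-specific 0.8 restriction leaves a near-null fit
in which most coefficient rows are exactly zero; such a matrix is rejected
by the affinity construction's degeneracy guard, so the restricted grid
cannot feed the network stage at all. The 0.8 default remains in the API.

## From coefficients to networks

Rows of B are feature profiles; columns are trait profiles (the trait-side
network of B is exactly the feature-side network of Bᵀ). Profiles are
standardized dimension-wise, then converted to a scaled-exponential kernel
affinity `W(i,j) = exp(−d²(i,j)/(α·ε_ij))` with locally adaptive bandwidth
`ε_ij = (mean_K(i) + mean_K(j) + d(i,j))/3`, where mean_K is the mean
Euclidean distance to the K nearest neighbors. This is the similarity
network fusion (SNF) construction; it is the single biggest convention
inherited from that method. W(i,i) = 1; identical profiles get affinity 1 —
note that under sparse fits *all-zero* rows are mutually identical, which is
why a matrix with more than half its rows zero is rejected as degenerate.

Normalization yields the row-stochastic full kernel `P = D⁻¹W` and the KNN
local affinity S: each row keeps its K strongest off-diagonal affinities,
normalized to carry half the row mass, with the other half on the diagonal
(configurable off). KNN ties break by node order for determinism.

### Fusion

The cross-diffusion update for m networks generalizes the printed
two-network form by averaging the other m−1 status matrices:

    P(v) ← S(v) · (Σ_{u≠v} P(u) / (m−1)) · S(v)ᵀ,

followed by symmetrization and row renormalization each iteration (without
which the update drifts from stochasticity), for t = 20 iterations; the
fused network is the average of the m diffused matrices, symmetrized.
The update is invariant to the order of input networks and equivariant to
node permutation.

The (K, α) pair can be selected by maximizing the consensus score

    f(W, w_f) = mean_i SIM(w_f, w_i) + mean_{i<j} (1 − SIM(w_i, w_j)),

with SIM the Pearson correlation of vectorized off-diagonal upper triangles,
over K ∈ [2, 20], α ∈ [0.3, 0.8]. The second term does not involve w_f; it
is implemented exactly as written above and acts through the (K, α) dependence of
the inputs. Ties break toward smaller K, then smaller α. The pipeline
default is K = 20, α = 0.5 without the grid (the grid rebuilds affinities
and the fusion for every cell and is opt-in for cost reasons).

### Permutation cutoff

For a network W the threshold c* minimizes, over a candidate grid,

    ½ [ mean_k E(WP_k^c)/E(W^c) + mean_k C(WP_k^c)/C(W^c) ],

where WP_k are networks with the upper-triangle weights shuffled uniformly
(symmetry, diagonal, and the weight multiset preserved), E counts edges with
weight ≥ c and C is the node count of the largest connected component;
100 permutations by default. Candidates are the empirical weight quantiles
at 0.5% steps, so the search adapts to scale (fused weights are orders of
magnitude smaller than raw affinities); candidates retaining no real edges
are excluded; ties break toward the larger (stricter) cutoff. E and C
curves are computed for all candidates in one descending union-find sweep
per permutation, and the per-candidate table is persisted so the objective
is reproducible from the artifacts.

Because weight shuffling preserves the weight multiset, the edge-count
ratio is identically 1 and the criterion is driven entirely by the
component ratio: the argmin rewards cutoffs at which the real network's
surviving weights are more *concentrated* than random placement. On
networks whose strong edges are spread uniformly inside communities this
drives the selected cutoff toward the extreme sparse end rather than the
community/background gap — a structural property of this selection rule
under a multiset-preserving null, documented here because it limits what
"retained edges" mean on such inputs. The verbal selection rule sometimes
quoted alongside the formula (permuted edge count below the real one) can
never hold strictly under this null; it is reported as a per-candidate
sanity column, not used for selection.

## Network diagnostics

`network_properties` reports node/edge counts, density 2E/(N(N−1)),
diameter of the largest component (BFS), mean local clustering over nodes
of degree ≥ 2 (the global triangle ratio is reported alongside), average
neighbors 2E/N, component count (union–find), and the scale-freeness score:
R² of the least-squares line through (log10 degree, log10 frequency) over
the unbinned distinct-degree table (≥ 3 distinct degrees required). The
graph quantities are implemented directly and cross-checked against
networkx in the tests. The correlation-network baseline connects column
pairs whose Pearson test p-value (t distribution, n−2 df) falls below
0.01 divided by the number of pairs, with |r| weights. `top_k_overlap`
ranks |β| entries (ties by feature then trait id), collects each method's
top-k (feature, trait) pairs, and reports all intersection sizes of the
implicated feature sets plus the count of features found by ≥ 3 methods.

## Synthetic data

`simulate.generate` draws: features in equal-sized groups sharing a Gaussian
factor (within-group correlation ρ); a sparse B whose per-trait support
(5% of J) is drawn inside 2 feature groups per trait block and *shared* by
all traits of the block (per-trait magnitudes jittered by 5%), with signs
random and |β| ~ U(0.5, 1.5); noise correlated within trait blocks at the
same ρ; Y = XB + ε, then both matrices standardized. The default scenario
is n = 100, J = 200, K = 50, 10 feature groups, 5 trait blocks, ρ = 0.8,
σ = 0.5.

What this emulates: standardized inputs, group-structured features
recoverable by Ward clustering, trait blocks whose correlation graph at
threshold 0.7 is non-trivial, and group/graph-aligned sparse effects. What
it does not emulate: bounded methylation beta-value distributions, batch
effects, heavy-tailed expression noise, and — importantly — the weak-signal
regime of real tumor cohorts. With ten effects of unit-order size per
trait, the planted signal carries ~97–99% of trait variance, so *all* four
estimators fit near the noise floor and the relative MSE ranking between
them is dominated by their bias at the selected penalty rather than by the
value of structural information; passing tests on this generator therefore
demonstrate correctness of each estimator and of the pipeline plumbing, not
that structure improves prediction on weak-signal data.

## Numerical choices and limitations

- SD denominator n−1 everywhere; missing values rejected at read time.
- Ward.D2 (scipy `linkage(method="ward")` on column vectors) for grouping.
- Sub-seeds per pipeline stage derive from the master seed via
  `SeedSequence([master, stage_index])`, so stages re-run independently.
- GFLasso's smoothing makes its solution accurate to O(μ·#fusion-terms);
  the continuation schedule keeps small-instance objective error below
  1e-4 at the default μ.
- The SIOL Dykstra prox runs to 1e-11 fixed-point change (≤ 60 inner
  iterations); outer monotone acceptance guarantees a non-increasing
  objective even under inexact proxes.
- Benchmark problem sizes: the acceptance suite runs the default scenario
  with 3-fold CV over 6-point paths and the network stage at K = 20,
  α = 0.5, t = 20, 100 permutations; brute-force solver oracles use
  J·K ≤ 4 instances.
- The fused matrix is returned in affinity form but its entries are
  diffusion averages, not kernel values; only relative weight matters for
  the downstream cutoff.
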