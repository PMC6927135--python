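# Methods

## Sampling model

The package treats a UMI count matrix (cells × genes, rows summing to
per-cell totals n_i) as multinomial samples of each cell's transcript pool:
cell i has relative abundances π_ij on the simplex and y_i ~
Multinomial(n_i, π_i). Consequences used throughout:

- the marginal of one gene is Binomial(n_i, π_ij) with mean μ_ij = n_i π_ij,
  variance μ_ij − μ_ij²/n_i, and zero probability (1 − μ_ij/n_i)^{n_i};
- the sum constraint induces a negative gene–gene correlation
  −√(π_j π_k)/√((1−π_j)(1−π_k)), reaching −1 with two genes;
- with many genes and no dominant one, the binomial marginals are nearly
  independent, and for large n_i each is approximately Poisson(μ_ij);
- extra biological variability is modeled by a symmetric Dirichlet on π_i,
  giving Dirichlet-multinomial counts whose per-gene marginals are
  approximately negative binomial with shape equal to the Dirichlet shape.

The Poisson zero probability is exp(−μ); the NB one is (φ/(φ+μ))^φ under
the shape parameterization var = μ + μ²/φ used everywhere in this package
(large φ ⇒ Poisson; the φ ↔ 1/φ ambiguity is resolved this way
deliberately and documented on `zero_probability` and `GLMPCA`).

## Estimators of relative abundance and the pseudocount identity

Per-cell MLE: π̂_ij = y_ij/n_i; pooled null MLE: π̂_j = Σ_i y_ij / Σ_i n_i.
With a symmetric Dirichlet(α_i) prior, the MAP is
(α_i + y_ij)/(Jα_i + n_i) = w_i/J + (1−w_i)π̂_ij, w_i = Jα_i/(Jα_i + n_i).
The standard transform log2(c + π̂_ij·m) equals log2 of the MAP at
α_i = (c/m)·n_i plus a constant that is global when c and m are fixed —
the pseudocount is a disguised prior, and with CPM (m = 10⁶, c = 1,
J ≈ 10⁴) its weight is only w ≈ 0.01, which is what produces the large
artificial gap between zeros and single counts at low depth. A property
test asserts this identity to 1e-10 on random matrices.

## Residuals

Under the pooled null (μ̂_ij = n_i π̂_j), the binomial deviance residual is

    r_ij = sign(y − μ̂) √( 2y log(y/μ̂) + 2(n − y) log((n−y)/(n−μ̂)) )

with term-wise 0·log 0 = 0 guards (no epsilons, so y = 0 and y = n are
exact), and the Pearson residual is (y − μ̂)/√(μ̂ − μ̂²/n). Squared deviance
residuals sum per gene to the closed-form deviance D_j (identity tested at
1e-8). Log-CPM z-scores are the Gaussian-null analogue, with MLE (1/I)
variance. All-zero genes have no defined null mean and are dropped with a
warning (error under `strict`); standardization (rescaling each gene's
residuals to unit sd, no centering) is available but off by default since
the formulas define unstandardized residuals. The `NullResiduals`
transformer learns π̂_j (and z-score moments) at fit time so new cells can
be transformed against a frozen null.

## Feature selection

D_j is computed in closed form from raw counts; D_j ≥ 0 with equality iff
the gene's proportion is constant across cells, and all-zero genes are
assigned D_j = 0 (constant at zero) so every method ranks the same gene
set. Baselines: highly expressed = mean raw count; highly variable =
CV² of CPM (variance of log-CPM behind a flag, since the common practice
varies). Ties break by gene index for reproducibility. Spearman
concordance between rankings uses average ranks for ties.

## GLM-PCA

Model: log μ_ij = log s_i + v_j1 + Σ_l u_il v_jl (+ covariate terms), with
y_ij Poisson or NB(φ). Size factors default to n_i. Design choices:

- **Objective.** Deviance plus an L2 penalty λ(‖U‖² + ‖V‖²) on the latent
  blocks only; intercepts and covariate coefficients are unpenalized.
  Default λ = 1 — a small penalty whose role is numerical stability, not
  shrinkage. The deviance carries the conventional factor 2 (twice the
  log-likelihood ratio) so it shares a scale with D_j and the residuals;
  the factor changes neither the argmin nor monotonicity.
- **Optimization.** Blockwise Fisher scoring iterating over latent
  dimensions: for dimension l, update all gene loadings V[:,l] holding
  factors fixed (independent one-parameter GLM steps per gene, expected
  information), then all cell factors U[:,l]. The intercept column is the
  l = 0 case with u_i1 ≡ 1. Any step that would increase the penalized
  deviance is halved up to 10 times and reverted if still failing, which
  makes the per-sweep deviance trace monotone by construction (asserted on
  50 random instances).
- **Initialization.** Intercepts at the closed-form Poisson GLM value
  log(Σ_i y_ij / Σ_i s_i); U, V i.i.d. N(0, (1e-2/√L)²) from the seeded
  generator. Convergence: relative change of penalized deviance < 1e-4
  (default) per sweep; max 1000 sweeps, returning `converged_=False` with
  a warning otherwise.
- **Dispersion.** NB shape φ is shared by default and re-estimated every 5
  sweeps by bounded 1-D likelihood maximization in log φ (per-gene mode
  optional). When the profile likelihood is flat toward φ → ∞ (no
  overdispersion), φ is set to a 1e6 ceiling with a warning. Shared φ is
  the default because the Dirichlet-multinomial approximation implies a
  single shape.
- **Covariates.** Cell covariates enter as fixed factor columns with free
  per-gene coefficients (batch labels one-hot, reference level dropped by
  the caller); gene covariates symmetrically.
- **Identifiability.** Factors are post-processed (without changing
  UVᵀ + intercepts beyond 1e-10): column means of U are absorbed into the
  intercepts, then a two-sided QR/SVD rotation makes factor columns
  orthogonal, ordered by singular value, with signs fixed so each column's
  largest-magnitude loading is positive. The operation is idempotent.
- **Offsets.** Scaling every cell's counts and size factor by a common
  constant leaves the unpenalized fit's loadings and intercepts unchanged
  from the same initialization (tested to 1e-6). Scaling a *single* cell
  re-weights that cell's contribution to the loading equations, so exact
  single-cell invariance does not hold and is not claimed.

`transform` for new cells runs damped Fisher scoring on the factor vectors
with loadings frozen.

## Synthetic data

Generators draw n_i, build π_i on the simplex, and sample multinomially;
identical seeds give bit-identical counts, and no global RNG state is
touched.

- **Null** (negative control): constant composition; defaults J = 10⁴
  uniform genes (π_j = 10⁻⁴), n_i uniform on [1000, 3000], I = 2000 —
  the regime where theory predicts ~74–90% zeros per gene.
- **Dirichlet-multinomial**: per-cell π_i ~ Dirichlet(αJ·π_base), giving
  overdispersion that grows as α shrinks.
- **Clusters + batches**: 150 cells in 3 clusters of 50; 5000 genes, 500
  informative; two batches with totals 1000 and 2000 and 25 cells per
  cluster per batch, so depth is the batch effect. Baseline abundances are
  log-normal(0, 2) (skewed, like real expression); informative genes get
  per-cluster log-normal(0, 1) multipliers before simplex renormalization.
  The effect scale is a knob (`effect_sd`) because no canonical value
  exists; an optional multiplicative gene-level batch effect is off by
  default.
- **Three gene classes** (for feature selection): 800 low, 100
  high-constant (50× the low abundance), 100 high-variable genes that
  swing 4-fold between two random halves of 250 cells with across-cell
  mean 0.8× the constant-high level — comparable pooled expression, but
  slightly below, as a gene alternating between high and lower states is.
  Only the variable class violates the null, so deviance should rank it
  first while mean expression ranks the constant class first.

What these simulations do **not** emulate: gene length/GC biases, PCR or
UMI-collision artifacts, read-count (non-UMI) distributions, doublets, or
continuous trajectories. Passing tests therefore demonstrate correctness
of the mathematics and the claimed qualitative behaviors under the stated
sampling model, not performance on any particular real dataset.

## Evaluation harness

PCA (full SVD, centered per gene, no rescaling), k-means (k-means++, best
of 10 restarts), adjusted Rand index, and Euclidean silhouette come from
scikit-learn behind the module surface; tests cross-check ARI against a
brute-force pair-counting oracle and silhouette against a brute-force
pairwise-distance computation. The grid runner crosses feature-selection
method × gene count × transform × latent dimension × cluster number,
spawning per-combination seeds from a master seed, and can filter results
to cluster numbers within 25% of the truth. Cells left with zero counts
after feature selection are dropped (they carry no information within the
selected gene universe).

## Problem sizes and numerical choices

Test and acceptance runs use the design sizes stated above (null
calibration at 2000 × 10⁴; clustering at 150 × 5000 over 10 seeds;
GLM-PCA recovery at 100 × 500, L = 2; diagnostics at 500 × 2000), chosen
as the smallest scales at which the Monte-Carlo assertions are stable.
Tolerances: simplex sums 1e-12; deviance identity 1e-8; pseudocount/MAP
identity 1e-10; closed-form intercept 1e-6; monotone trace slack 1e-6 per
sweep. Degenerate inputs (zero-total cells, all-zero genes, zero-variance
genes, μ̂ = n single-gene matrices, non-integer or negative counts) are
rejected or dropped with explicit messages rather than patched with
epsilons.

## Known limitations

Exact multinomial or Dirichlet-multinomial likelihoods for GLM-PCA are
intractable and not attempted; the Poisson/NB approximations stand in.
Dense arithmetic is used internally (residuals of zeros are nonzero, so
sparsity is lost after transformation anyway); very large matrices would
need a streaming backend. Negative-binomial-null Pearson residuals
(the sctransform approach) and highly-dropout gene selection are out of
scope. `transform` on new cells is an approximation that keeps loadings
fixed and is only offered for the Poisson likelihood path.
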