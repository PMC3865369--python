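# Methods

## Model and estimator

Expression in condition *t* is modelled as **Y**⁽ᵗ⁾ ~ N(*f*⁽ᵗ⁾(**X**),
(Ω⁽ᵗ⁾)⁻¹): the covariates **X** (marker genotypes) shift the mean through
an arbitrary, condition-specific *f*⁽ᵗ⁾, while gene–gene conditional
dependence lives in the precision matrices Ω⁽ᵗ⁾.  The estimator is
two-stage.

**Stage 1 — conditional covariance.**  The empirical conditional
variance operator between RKHSs of X and Y,

    Σ̂ = (1/n) ( YᵀQY − YᵀQ (QKQ)(QKQ)⁺ QY ),   Q = I − J/n,

with K the covariate Gram matrix and ⁺ the Moore–Penrose pseudoinverse.
`(QKQ)(QKQ)⁺` is exactly the orthogonal projector onto the column space
of the centered kernel, so the second term removes the part of centered
Y explained by covariate features.  With a linear kernel this equals the
moment formula S_YY − S_YX S_XX⁺ S_XY.  Both Y and X are always
mean-centered (equivalently, an intercept is included): the kernel
formula centers through Q regardless, and centering makes the two
routes agree exactly while leaving the linear-kernel estimate unchanged
for mean-zero data.  All moment matrices use divisor *n*.  Pseudoinverse
cutoff: singular values below 10⁻¹⁰ of the largest are treated as zero.
The RBF bandwidth defaults to the median pairwise distance.

A caveat worth knowing: with a strictly positive-definite kernel on
continuous covariates (e.g. RBF on real-valued X) the centered Gram is
numerically full rank and the projector removes *everything* — the
conditional covariance collapses to ~0.  This is the correct algebra,
not a bug; it is the finite-sample face of the estimator's known
inconsistency when the covariate space is too rich for the sample.  For
discrete genotypes the Gram rank is bounded by the number of distinct
genotype vectors and the estimator is well behaved.

**Stage 2 — joint sparse precision estimation.**  Minimize

    PPL({Ω}) = Σ_t n_t ( −log det Ω⁽ᵗ⁾ + tr(Σ̂⁽ᵗ⁾Ω⁽ᵗ⁾) ) + λ P({Ω}),

with the truncated-log joint penalty on a_jk = Σ_t |ω⁽ᵗ⁾_jk| (diagonal
excluded):

    P = Σ_{j≠k} [ (log a_jk − log ε + 1)·1{a_jk > ε} + (a_jk/ε)·1{a_jk ≤ ε} ].

Both branches equal 1 at a = ε, so P is continuous, with derivative
ζ_jk = 1/max(a_jk, ε).  ε = 10⁻³ throughout.  The concave log branch is
what couples conditions: once one condition supports an edge, the
marginal price for the others to share it is tiny.

Optimization is local linear approximation (LLA): at iteration k the
penalty is replaced by its tangent, giving T independent weighted
graphical-lasso subproblems

    min_Ω  tr(Σ̂⁽ᵗ⁾Ω) − log det Ω + (λ/n_t) Σ_{j≠k} ζ⁽ᵏ⁾_jk |ω_jk|

(the LLA display divided by n_t, so the inner solver sees one scale).
LLA is majorize–minimize: with accurate inner solves the PPL objective
is non-increasing, which the implementation records (`objective_path`)
and the tests assert.  LLA stops when the relative Frobenius change of
all Ω⁽ᵗ⁾ falls below 10⁻⁴, after at most 50 iterations.

## Inner solver

The weighted graphical lasso with element-wise penalties is solved by
block coordinate descent over columns (the classical covariance-update
algorithm), each column's lasso subproblem by coordinate descent with a
per-element penalty vector; the hot loops are numba-compiled.  The
diagonal is never penalized.  Convergence is declared when the mean
absolute change of Ω over a sweep drops below tol·mean|S_offdiag|
(tol = 10⁻⁵) *and* the KKT residual — the max-norm violation of the
subgradient stationarity conditions — is below tol·(1 + max|S|).
Capped LLA weights (1/ε = 1000) are handled as ordinary large finite
weights.  λ = 0 with positive-definite S reproduces S⁻¹ exactly after
one sweep.  Correctness is cross-checked two ways: against
scikit-learn's `graphical_lasso` for scalar penalties (same
off-diagonal-only convention) and against an independent FISTA
proximal-gradient oracle for element-wise weights.

**Degenerate inputs.**  When Σ̂ is rank deficient (n ≤ p + q) the
penalized likelihood is nearly unbounded at small λ: iterate entries
grow along null directions and coordinate descent crawls.  The solver
detects stagnation (changes tiny relative to the iterate, or slow
geometric decay with entries dwarfing S) and stops, flagging the result
unconverged; the LLA loop likewise stops after three consecutive
iterations whose inner solves cannot be certified.  Such fits still
participate in model selection — that is what the data look like — but
their exact edge counts depend on these iteration budgets, and any
quantity computed in this regime should be read qualitatively
("collapse"), not to three decimals.

## Initialization and the λ path

Each λ is fitted from the dense initialization Ω₀⁽ᵗ⁾ = (Σ̂⁽ᵗ⁾ + δI)⁻¹,
where δ = 10⁻³ is added repeatedly until the eigenvalue ratio is at most
10³ (and the matrix is invertible).  Two properties of the nonconvex
penalty drove this design, both observed directly during development:

* an **empty warm start is absorbing** — with all weights capped at 1/ε
  no edge can re-enter at any useful λ;
* a **dense warm start at small λ is equally sticky** — weights stay
  tiny and nothing is ever removed.

Warm-starting along the path therefore destroys it, and every λ gets the
same dense start instead.  From a dense start the first LLA weights are
≈ 1/|ω̂₀|, i.e. adaptive-lasso-like, which is also why the fits are
nearly unbiased on kept edges.

The default grid is 32 log-spaced values from λ_max = max_t n_t ·
max_{j≠k}|Σ̂⁽ᵗ⁾_jk| (which empties the graph from the dense start) down
to λ_max·10⁻⁴.  BIC
(Σ_t{−log det Ω̂ + tr(Σ̂Ω̂) + log(n_t)·df_t/n_t}, df counting nonzero
upper-triangle entries including the diagonal at the 10⁻⁶ edge
threshold) selects λ; ties go to the larger (sparser) λ.  Descending the
grid, the search stops after six consecutive strictly-worse BIC values
past the incumbent, and after three consecutive numerically invalid
fits; in all non-degenerate paths inspected the argmin is interior and
unaffected, while in the degenerate small-n regime BIC decreases
monotonically into the collapse and the search correctly runs to the
deepest valid λ.

Because the problem is nonconvex these are local solutions; the
objective path is exposed and the initializer is replaceable, but no
multi-start is performed by default.

## Separate baselines

The benchmark's separate fits (`ggm`, `cggm`) are the T = 1 special case
of the same truncated-log estimator, each condition with its own BIC, on
the marginal and conditional covariance respectively — so the four-way
comparison isolates exactly two design axes, conditioning and jointness.
A plain scalar-penalty graphical-lasso path (`scalar_glasso_path`) is
provided for reference; note that with lasso shrinkage the in-sample
likelihood keeps improving along the path and BIC then selects much
denser models than it does for the nearly unbiased nonconvex fits.

## Simulation benchmark

The generator reproduces a genetical-genomics backcross study:

* **Map/genotypes**: one 1000 cM chromosome, 10 equally spaced markers
  (spacing ≈ 111 cM, adjacent-marker recombination ≈ 0.446 by the
  Haldane map r = (1 − e^(−2d/100))/2), genotypes a 0/1 Markov chain per
  individual.
* **Networks**: common structure by preferential attachment (one edge
  per new node) from a 6-edge path seed on 7 nodes → 29 common edges at
  p = 30; each condition adds round(0.1·29) = 3 private edges.  The
  common graph is a tree.
* **Precisions**: edge weights Unif([−1,−0.5]∪[0.5,1]), diagonal = sum
  of absolute off-diagonals (isolated nodes get 1).  Equality-dominant
  matrices are singular whenever the edge signs are consistent — on a
  tree always — so draws are rejected and resampled until the smallest
  eigenvalue exceeds 10⁻⁸; the private edges' cycles make acceptance
  quick.  Accepted matrices are still near-singular (smallest eigenvalue
  typically 0.01–0.05), which is what makes the inference problem
  nontrivial.
* **Expression**: Y⁽ᵗ⁾ = X B⁽ᵗ⁾ᵀ + E⁽ᵗ⁾, E rows N(0, Ω⁽ᵗ⁾⁻¹) drawn by
  Cholesky back-substitution.  Case 1: three isolated coefficients per
  condition at (gene, marker) = (1,1), (2,4), (3,8), values
  (−0.09, 0.789, −0.667), (1.361, 1.508, −2.608), (0.687, 0.316, 2.020)
  per condition.  Case 2 (hotspots): genes 1–18 on marker 1, 19–25 on
  marker 4, 26–30 on marker 8, coefficients = the condition's Case-1
  triple + N(0, 0.1²).
* **Replication**: the map is fixed; genotypes, network, precisions,
  Case-2 coefficients and noise are redrawn per replicate from spawned
  seed streams, so a run is exactly reproducible from one integer seed.

What the generator does *not* emulate: measurement error and
normalization artefacts of expression arrays, linkage disequilibrium
structure beyond a single chromosome, polygenic mean effects, missing
data, or any mismatch between the Gaussian model and real expression
distributions.  Passing benchmarks here demonstrates correct recovery
under the model's own assumptions, not robustness to their violation.

## Evaluation

FP and FN are per-condition edge error rates (upper triangle, truth =
generative adjacency, estimate thresholded at |ω| > 10⁻⁶), averaged over
conditions; FPC/FNC are the analogous rates on across-condition common
zeros / union edges; RFL = (1/T) Σ_t ‖Ω⁽ᵗ⁾ − Ω̂⁽ᵗ⁾‖²_F / ‖Ω⁽ᵗ⁾‖²_F.
ROC paths evaluate the whole λ grid without selection and are averaged
across replicates at matched grid indices.  Tables report means with
standard errors sd/√(replicates).

## eQTL scan

Marker regression per gene: LOD = (n/2)·log₁₀(RSS₀/RSS₁), capped at 50
for numerically perfect fits; monomorphic markers score 0 with a
warning.  Genome-wide thresholds are per-gene 95th percentiles (linear
interpolation) of the max-over-markers LOD across 1000 permutations of
that gene's expression vector (genotypes fixed).  Covariates are the
union over genes of markers exceeding their gene's threshold.  LOD is
invariant to affine trait rescaling, so thresholds are too.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| ε | 10⁻³ | penalty truncation; caps LLA weights at 1/ε |
| λ grid | 32 values, λ_max → λ_max·10⁻⁴ | λ_max = max_t n_t·max offdiag |Σ̂| |
| edge threshold | 10⁻⁶ | |ω| above this counts as an edge (df, metrics, output) |
| δ ridge / cond. trigger | 10⁻³ / 10³ | initialization (Σ̂+kδI)⁻¹ |
| LLA tol / max iter | 10⁻⁴ / 50 | relative Frobenius stopping rule |
| wglasso tol / max sweeps | 10⁻⁵ / 100 | change + KKT certificate |
| scan permutations / α | 1000 / 0.05 | genome-wide thresholds |

## Problem sizes used in the shipped studies

The acceptance script runs the three study scenarios (Case 1 n = 100,
Case 1 n = 30, Case 2 n = 100) at 50 replicates each with the defaults
above.  End-to-end tests use 3–20 replicates and, where noted, a coarser
16-point λ grid — path resolution, not estimator behaviour, is what is
reduced.

## Known limitations

* Nonconvexity: all guarantees are local; a different initializer can
  give a different network at the same λ.
* The degenerate small-sample conditional regime (n ≤ p + q) is reported
  honestly but its dense "collapse" fits are iteration-budget-dependent;
  only their qualitative blow-up is meaningful.
* BIC with the T = 1 lasso baseline over-selects dense models (see
  above); the shipped baselines avoid this by using the nonconvex
  penalty, but users plugging in their own scalar-lasso path should
  expect it.
* The conditional covariance requires a covariate set that is small
  relative to n; no automatic covariate selection is performed inside
  the fit (use the eQTL scan module, as the real-data workflow would).
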