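# Methods

## Model and constraint

All estimators fit the factor decomposition

```
X ≈ F A' + U Ψ,     Z = [F U],   (1/n) Z'Z = I_(r+p)
```

to a column-centered n×p data matrix, treating the scores as parameters.
The scaled-orthonormality constraint standardizes every score column to
variance 1 and makes common and unique scores mutually orthogonal, which is
what allows uniquenesses to be read off as `ψ_j = (1/n) u_j'x_j`.  Centering
is performed by the data readers, never silently inside estimators;
estimators validate and fail on non-centered input.  Construction requires
n > p + r so that an n×(r+p) column-orthonormal block exists.

## Score indeterminacy and the penalized estimators

At any fixed (A, Ψ) the constrained least-squares scores solve an
orthogonal-Procrustes problem via the SVD of `X[A, Ψ] = PΛQ'`; since this
product block has rank at most p, exactly r singular values vanish and the
corresponding left vectors are free.  `decompose_scores` returns the
determinate parts (linear in X), an orthonormal basis `basis_perp ⊥ col(X)`,
and the fixed null-space mixing blocks; every orthogonal rotation of the
free basis yields a valid score set with identical loss
(`ScoreDecomposition.score_variant` / `score_with_basis`).

RFE removes the freedom by adding `α‖Y − FB'‖²` for external criteria Y.
The augmented objective collapses to a single Frobenius discrepancy
`‖[X, √α Y] − ZW'‖²` with `W = [A, Ψ; √α B, 0]`, so the same SVD update
applies and — when q ≥ r with full-rank B and full-rank product block — has
a unique maximizer.  The identity `rfe_loss = penalized_form_loss + α‖Y‖²`
(an L2 penalty on B minus a score-criterion covariance term) is kept as a
runtime-checkable reformulation.  The uniqueness and observed-space
diagnostics live in `check_identification`: rank checks plus the projection
residual of F onto col([X, Y]), which is ~1e-14 for identified fits.

CFE replaces the criteria block by the K-means reconstruction `MC'` with its
coefficient block fixed to the identity.  CCFE is the two-stage baseline:
plain MDFA, then alternation of K-means steps with an exact Procrustes
update of the **entire free score block** over the Stiefel manifold
orthogonal to col(X) (closed form via the projected SVD of
`Π⊥(MC' − F_det)Jf'`).  Restricting the baseline to an r×r rotation of a
fixed basis would only rigidly rotate the free cloud and could not produce
the cluster-carving behaviour that motivates comparing the methods, so the
full indeterminacy class is used.

## Algorithm and numerical choices

* Every substep is an exact conditional minimizer, so the loss is
  non-increasing by construction; any numerical increase beyond
  1e-9·(1+loss) raises an internal-consistency error rather than being
  silently accepted.
* Convergence: absolute loss decrease below `tol · ‖[X, √α Y]‖²` with
  default `tol = 1e-7`, `max_iter = 1000`.  Exactness tests use
  `tol` down to 1e-18 to converge to machine precision on noise-free data.
* Initialization per start: principal-component loadings plus Uniform(−0.1,
  0.1) jitter, `ψ₀ = 0.5 ×` column standard deviations, B = 0; start *i*
  uses seed `seed + i`.  B = 0 makes the first score update's free
  directions arbitrary; the rank-deficiency flag therefore reflects the
  final iterate only.
* Defaults: `α = 0.01`, 20 starts.  The semi-automatic grid heuristic
  (`select_alpha`) scans {0.01, 0.05, 0.1, 0.5, 1, 5} in increasing order
  and returns the smallest value whose fitted loadings stay within 0.05
  aligned RMSE of the plain MDFA loadings — i.e. the smallest weight that
  pins the scores without distorting the factor solution.
* Local solutions: a start counts as local when its converged loss exceeds
  the best by more than 1e-4 relative.  On low-noise data, distinct solution
  families can sit within ~5e-4 relative of each other, so small nonzero
  proportions can reflect genuinely shallow splits rather than optimizer
  failures.
* K-means substeps: equidistant ties assign to the lowest-index centroid; an
  empty cluster is re-seeded at the point farthest from its assigned
  centroid (never increases the objective).
* SVD ties (equal singular values) make the score update non-unique; the
  update accepts any valid decomposition and flags rank-deficient product
  blocks.
* Geomin rotation: oblique gradient projection with ε = 0.01, 30 starts
  (identity first), unit-column normalization of T, `Phi = T'T`; loadings
  transform as `A(T')⁻¹` and scores as `FT`, preserving `FA'` exactly.
  Convergence is declared at projected-gradient norm 1e-5; on loading
  matrices without approximate simple structure the algorithm may stop at
  `max_iter` with a warning and return the best iterate.
* Alignment for recovery scoring: the fitted loss is invariant under a joint
  orthogonal rotation of (F, A, B), so estimates sit at an arbitrary point
  of their orbit.  Recovery errors therefore align the estimated loadings to
  the truth by orthogonal Procrustes and apply the same rotation to F and B.
  The permutation/sign search (used when the orientation is already fixed)
  solves the assignment problem exactly for any r because the squared error
  separates per target column.
* Cohen's d uses the pooled SD and the large-sample normal CI
  `d ± z·√((n1+n2)/(n1 n2) + d²/(2(n1+n2)))`.
* Bartlett scores use the weighted-least-squares form
  `XΨ⁻²A(A'Ψ⁻²A)⁻¹`; a factor correlation matrix is accepted and validated
  for interface parity with oblique loadings but does not enter the
  estimator.  Near-zero uniquenesses make the weights singular and raise an
  error naming the variable.

## Synthetic designs

`generate_dataset` (recovery study): true scores are the left singular
vectors of a column-standardized Uniform(0,1) block scaled by √n — the
constraint holds exactly.  Loadings follow a perfect simple structure with
nonzeros Uniform(0.5, 1.0) and random signs; true uniqueness square roots
are 0.5; regression coefficients are dense Uniform(0.5, 1.0) with random
signs.  Standard-normal errors are rescaled so the explained-variance
proportion equals ρ *exactly* (`scale_error_to_rho`); the grid used in the
study is ρ ∈ {0.5, 0.7, 0.9} with defaults n = 200, p = 12, r = q = 3.
Desk-scale runs use 20 replications per condition.

`generate_nocluster_demo`: six variables, two factors, fixed loadings 0.8 on
one factor each, uniqueness square roots 0.6 (unit-communality convention),
residuals Uniform(−1, 1), n = 200.  `generate_clustered_demo` plants k
centroids at regular-simplex vertices (pairwise distance = `separation` in
within-cluster SD units), scatters members with unit Gaussians, and obtains
exactly valid scores by symmetric (closest-matrix) orthonormalization, which
preserves the planted structure; X is built through the same loading
construction with ρ-scaled Gaussian error.

What these designs do **not** emulate: ordinal/Likert marginals, missing
data, heteroscedastic uniquenesses across variables, cross-loadings, and
factor correlations in the truth.  Passing tests therefore demonstrate
correctness of the estimators and their contracts, not robustness to those
real-data features.

## Known limitations and observed behaviour

* Score-matrix recovery has an irreducible noise floor: individual scores
  are n×r quantities estimated from noisy rows, so their RMSE cannot fall
  below ≈0.3 at 90% explained variance regardless of estimator.  Loadings,
  coefficients and uniquenesses do reach median RMSE < 0.1 there; exact
  score recovery is verified on noise-free data instead.
* Joint-vs-two-stage cluster contrast: with the demo constants above, the
  exact-minimizer CFE aligns its free score component to the cluster
  reconstruction for *any* positive α (the free directions of the augmented
  product block carry singular values proportional to α but are resolved
  exactly), so its clusters on structureless data come out at least as
  cohesive as CCFE's, whose squeeze is capped by the free-energy fraction of
  the scores (≈25% here).  The relative cohesiveness of the two methods is
  therefore sensitive to the demo's loading/uniqueness constants, which
  govern that fraction.
* Both clustering penalties can relocate a handful of boundary observations:
  moving a row's free score component is exactly free for the
  factor-fit term, so an early misassignment can be cemented.  Planted
  three-cluster recovery saturates around 95% membership agreement rather
  than 100%, and CFE/CCFE mutual agreement around 90%.
* The local-solution proportion is threshold-based (1e-4 relative) and can
  register shallow near-ties as local solutions on some datasets.
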