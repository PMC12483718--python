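# facscore

Exploratory factor analysis with **uniquely determined factor scores**, built
on matrix-decomposition factor analysis (MDFA).

## The problem

The factor model explains a column-centered data matrix *X* (n observations ×
p variables) through r common factors:

```
X ≈ F A' + U Ψ,      (1/n) [F U]'[F U] = I
```

with common scores *F* (n×r), unique scores *U* (n×p), loadings *A* (p×r) and
a nonnegative diagonal *Ψ* of uniqueness square roots.  MDFA fits this model
directly to *X* by least squares — but the optimal scores are **not unique**:
they split into a determinate part (a linear combination of *X*'s columns)
and a freely rotatable component orthogonal to col(*X*).  Whenever individual
scores are of substantive interest — comparing groups, screening outliers,
clustering people — that indeterminacy matters.

`facscore` implements penalized estimators that remove it:

* **RFE** (regression-based factor score exploration) augments the loss with
  a multivariate-regression term for external criteria *Y* (n×q):
  `‖X − FA′ − UΨ‖² + α‖Y − FB′‖²`.  With q ≥ r criteria and full-rank
  coefficients the fitted scores are unique and lie in col([X, Y]).
* **CFE** (clustering-based factor exploration) replaces the regression term
  with a K-means penalty `α‖F − MC′‖²`, jointly clustering the scores during
  estimation.
* **CCFE**, the earlier two-stage baseline: fit plain MDFA, then choose the
  free score component to best match a K-means structure.  Because that
  choice answers only to the clustering objective, CCFE can carve cluster
  structure out of data that has none — the failure mode the joint methods
  are designed to expose.

All estimators use alternating least squares in which every step is an exact
conditional minimizer (an orthogonal-Procrustes/SVD score update, closed-form
uniqueness and coefficient updates), so the loss is provably non-increasing
and the score constraint holds at every iterate.  Multi-start fitting reports
the converged loss of every start and the proportion of local solutions.
Post-fit tooling includes oblique geomin rotation with consistent
counter-rotation of scores and coefficients, orthogonal Procrustes alignment,
Bartlett post-hoc scores, Cohen's *d* group contrasts with confidence
intervals, per-observation residuals, and exact-`ρ` synthetic data
generators.

## Worked example

```python
import numpy as np
import facscore as fs

# 200 observations, 12 variables, 3 factors, 3 external criteria,
# error scaled so the model explains exactly 50% of the variance
data, truth = fs.generate_dataset(
    fs.SimulationDesign(n=200, p=12, q=3, r=3, rho=0.5, seed=7))

fit = fs.fit_rfe(data, r=3, config=fs.AlgoConfig(alpha=0.01, n_starts=20, seed=0))
print(f"converged: {fit.converged} after {fit.n_iter} iterations")
print(f"best loss: {fit.best_loss:.3f}")
print(f"local-solution proportion: {fit.local_solution_proportion:.2f}")

report = fs.check_identification(data, fit.params, fit.scores, alpha=0.01)
print(f"scores unique: {report.unique}, "
      f"projection residual: {report.projection_residual:.2e}")

A_aligned = fs.align_for_rmsea(fit.params.A, truth.params.A, mode="procrustes")
print(f"loading recovery error (RMSEA): {fs.rmsea(A_aligned, truth.params.A):.4f}")

rot = fs.geomin_rotate(fit.params.A, F=fit.scores.F, seed=0)
print("geomin-rotated loadings (first 4 of 12 variables):")
print(np.round(rot.A_rot[:4], 3))
```

prints

```
converged: True after 14 iterations
best loss: 21.033
local-solution proportion: 0.00
scores unique: True, projection residual: 1.95e-14
loading recovery error (RMSEA): 0.0816
geomin-rotated loadings (first 4 of 12 variables):
[[ 0.023  0.04  -0.634]
 [ 0.159 -0.011  0.89 ]
 [-0.077 -0.     1.028]
 [-0.025 -0.055 -0.828]]
```

The projection residual ≈ 0 confirms the fitted scores are a linear
combination of the observed variables in [X, Y] (they would not be for
post-hoc estimators, which use X alone).  The recovery error says the
loadings sit within 0.08 root-mean-square of the generating truth even at
50% noise.  The rotated loadings show the recovered simple structure: each
variable loads on a single factor.

## Command line

```
facscore fit --method rfe -x X.csv -y Y.csv -r 3 --alpha 0.01 --out results/
facscore fit --method cfe -x X.csv -r 2 -k 3 --out results/
facscore simulate --rho 0.5 --replications 20 --out report.csv
facscore rotate -a results/loadings.csv --out rotated/
facscore scores -x X.csv -a loadings.csv --psi psi.csv --out F.csv
facscore cluster-stats -f F.csv -m membership.csv
```

`fit` writes loadings, uniquenesses, coefficients, scores, memberships, the
loss trajectory, per-start losses and a YAML manifest; identical
configuration and seed reproduce byte-identical outputs.

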