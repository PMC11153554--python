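# sgtm-cascade

Non-iterative neural-like regression for tabular biomedical data, built on
**successive geometric transformations** (SGTM), **Kolmogorov–Gabor
polynomial input expansion**, and a **cascade ensemble** whose levels are
chained through their own predictions — plus an exact transition from the
fitted "neural" form to an explicit, human-readable polynomial.

## Who it is for and what it does

The package targets regression problems of the kind common in
epidemiological and physiological monitoring (e.g. predicting heart rate
from 18 biomedical indicators): large numeric tables, a smooth nonlinear
response, and a need for models that train fast and can be audited as
formulas rather than opaque weight tensors.

The core pieces:

1. **SGTM neural-like structure** (`sgtm_cascade.sgtm`). Training performs a
   pivoted Gram–Schmidt sweep over the sample vectors: at step *S* the
   largest-norm residual row `x_b^(S)` becomes a unit base direction, each
   row's projection coefficient

       k_i^(S) = x_i^(S) · x_b^(S) / ‖x_b^(S)‖

   is recorded, and the component is subtracted,
   `x^(S+1) = x^(S) − k^(S) x_b^(S)`. The directions are orthonormal, the
   coefficients are principal-component-like hidden signals sorted by
   importance, and for full-rank data the residual vanishes in *p* steps, so
   decomposition/reconstruction is exact. In supervised mode the sweep runs
   on the column-augmented matrix `[X | y]`; at prediction time the unknown
   output coordinates are estimated from the input parts of the base
   directions and rescaled by least-squares corrections `α^(S)`
   (`k̃^(S) = α^(S) k^(S)`), fitted jointly so that the full-rank model
   coincides with ordinary least squares. Truncating to the first *m* steps
   ("hidden neurons") filters low-importance noise components.

2. **Kolmogorov–Gabor expansion** (`sgtm_cascade.expansion`). The inputs are
   lifted to all monomials of total degree ≤ k (default k = 2), turning each
   SGTM level into a polynomial regressor; for n inputs the quadratic
   expansion has `n + n(n+1)/2` columns.

3. **Cascade** (`sgtm_cascade.cascade`). The training set is split into L
   disjoint blocks. Level 1 fits the expanded block 1. Every later level
   pushes its own block through the earlier chain, appends the previous
   level's prediction `y_prev` as one extra attribute, re-expands, and fits
   against the true targets. Each level stays linear-in-parameters, yet the
   composition is a polynomial of degree 2^L in the original inputs —
   response-surface linearisation.

4. **Interpretability** (`sgtm_cascade.interpret`). Each trained level is
   affine in its scaled expanded features, so probing it with a diagonal
   matrix of test signals (the zero vector plus unit vectors) reads off its
   coefficients exactly. Folding in the max-abs scaling gives per-level
   polynomials in raw variables, and symbolic substitution of `y_prev`
   composes the whole cascade into one explicit polynomial.

5. **Model selection** (`sgtm_cascade.evaluation`). Four error metrics
   (maximum residual, MAE, MSE, median absolute error), optimal-complexity
   depth selection (grow the cascade until the held-out error stops
   decreasing), a brute-force hidden-neuron sweep, and k-fold CV.

## Worked example

```python
import numpy as np
from sgtm_cascade import (CascadeConfig, SyntheticSpec, cascade_predict,
                          compose_polynomial, compute_metrics, fit_cascade,
                          make_polynomial_dataset, poly_degree,
                          select_optimal_levels, split_train_test)

ds, truth = make_polynomial_dataset(
    SyntheticSpec(n_samples=4000, n_features=2, degree=4, noise_sd=0.05, seed=7))
train, test = split_train_test(ds, test_fraction=0.30, seed=0)

errors = []
for L in (1, 2, 3, 4):
    model = fit_cascade(train, CascadeConfig(levels=L, degree=2, seed=0))
    report = compute_metrics(test.y, cascade_predict(model, test.X))
    errors.append(report.mae)
    print(f"levels={L}  MAE={report.mae:.4f}  MSE={report.mse:.4f}")

print("optimal depth:", select_optimal_levels(errors))
model = fit_cascade(train, CascadeConfig(levels=3, degree=2, seed=0))
print("composed degree:", poly_degree(compose_polynomial(model)))
```

Output:

```
levels=1  MAE=0.2780  MSE=0.1306
levels=2  MAE=0.2007  MSE=0.0707
levels=3  MAE=0.1898  MSE=0.0676
levels=4  MAE=0.1952  MSE=0.0711
optimal depth: 3
composed degree: 8
```

The target is a noisy degree-4 surface. One quadratic level underfits;
depth 2 and 3 cut the held-out MAE by ~30%; at depth 4 the per-level blocks
get too small and generalisation degrades, so the optimal-complexity rule
picks 3 levels. The 3-level chain, composed symbolically, is a single
degree-8 polynomial (2³) in `x1, x2` that reproduces the neural form's
predictions to ~1e-14.

The same pipeline is available from a shell:

```bash
sgtm-cascade simulate --kind polynomial --features 2 --degree 4 \
    --noise-sd 0.05 --n 4000 --seed 7 --out data.csv
sgtm-cascade train --data data.csv --target y --levels 3 --seed 0 --out model.json
sgtm-cascade predict --model model.json --data data.csv --out pred.csv
sgtm-cascade extract-poly --model model.json --out poly.csv
```

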