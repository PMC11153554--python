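# Methods

This note documents the model, the numerical choices, and the limits of
what the test suite demonstrates.

## The SGTM decomposition

Given a training matrix with rows `x_i ∈ R^p`, columns are centred by their
means and the following sweep runs for at most `p` steps:

1. pick the residual row with the largest Euclidean norm (ties go to the
   smallest row index — a deterministic, testable rule);
2. normalise it to a unit base direction `d_S` and record the pre-normalisation
   norm (`base_norm`);
3. record each row's projection coefficient `k_i = r_i · d_S` and subtract
   `k_i d_S` from every row.

This is pivoted Gram–Schmidt on the sample vectors. Consequences relied on
throughout: the `d_S` are orthonormal; `base_norm` is non-increasing in `S`
(projection cannot grow a row); for full-rank data the residual is zero
after `p` steps, so `x̂ = mean + Σ_S k_S d_S` reconstructs the training
matrix exactly; and the `k` coordinates resemble principal-component scores
(the pivot chases the longest axis of the scatter at each step) without the
cost of an eigendecomposition. Training is entirely non-iterative and
deterministic: refitting on identical input is bit-identical.

Rank handling: step creation stops when the best base norm falls below
`1e-10 ×` the largest initial row norm; rank-deficient data simply yields
fewer steps, never an error.

## Supervised mode

The sweep runs on the centred augmented matrix `Z = [X | y]`, where the base
selection uses the full augmented norm (outputs are known for training
vectors, and including them lets target-correlated directions be picked
early). That fixes orthonormal directions `d_S = (d_in,S, d_out,S)`.

At prediction time the output coordinates are unknown, so the hidden signal
of step `S` is estimated from inputs alone:

    k_in,S = (r · d_in,S) / ‖d_in,S‖²,   r ← r − k_in,S d_in,S,

i.e. the exact projection coefficient on the input part, with the component
removed before the next step (directions whose input part is numerically
zero are skipped — nothing about them is recoverable from inputs). The
prediction is

    ŷ(x) = mean(y) + Σ_S α_S k_in,S d_out,S.

The corrections `α_S` are computed by least squares: because the scores
`k_in,S` do not depend on `α`, all corrections can be fitted jointly in one
small linear solve against the training outputs. When the score columns are
uncorrelated this reduces to the per-step ratio `Σ k k_in / Σ k_in²`; in
general the joint fit is what makes the construction an honest least-squares
method — at full rank the fitted affine map coincides with ordinary least
squares to machine precision, and on noiseless linear targets recovery is
exact. We validated per-step marginal fitting and several alternative
prediction recurrences on a 500×5 linear benchmark; all leave large
systematic error (relative RMSE 0.02–0.57 on noiseless data), so the joint
fit is the package's design.

Truncation: keeping only the first `m` steps (the "hidden neurons"
hyperparameter) regularises like principal-component regression — the sweep
generates directions in descending importance, and the α refit uses only the
retained ones.

Degenerate cases: a zero-variance augmented matrix yields zero steps, i.e.
the mean predictor; a constant target makes every `d_out` zero and the
prediction is exactly the constant; `Σ k_in²` underflow simply leaves that
step's feature column zero, so its α contributes nothing.

## Input expansion

`kg_expand` lifts `n` inputs to all monomials of total degree `1..k`
(no constant column — the intercept is carried by centring). The count is
`C(n+k, k) − 1`; for the default `k = 2` that is `n + n(n+1)/2` (18 inputs →
189 columns). The monomial order is frozen — ascending total degree, then
graded-lexicographic — so serialised models are portable; the first `n`
columns are always the raw variables. Degrees above 2 are supported for
experimentation but are not the default: the column count explodes and the
extra capacity is better obtained by cascade depth.

## The cascade

Training partitions the data into `L` disjoint, near-equal blocks (seeded
shuffle, remainder rows to the earliest blocks). Level 1: expand block 1,
fit a max-abs scaler on the expanded matrix, fit a supervised SGTM. Level
`ℓ > 1`: run block `ℓ` through levels `1..ℓ−1` in pure inference mode,
append the resulting prediction as the single extra attribute `y_prev`,
expand the `(p+1)`-dimensional vectors, scale, fit against the block's true
targets. Application mode repeats the same chain. Only the latest
prediction is appended at each level — that is what makes the composed
degree double per level (`2^L` for quadratic expansions) rather than
accumulate attributes.

Choices worth stating:

* **Scaler placement.** One max-abs scaler per level, fitted on that level's
  *expanded* training block (including the appended `y_prev` column).
  Expansion products have wildly different ranges; scaling after expansion
  is what keeps the max-norm pivot meaningful. The target itself is never
  scaled, only centred inside the SGTM.
* **Blocks are disjoint and used once** (no repetition across levels), and
  the hidden-neuron count is shared by all levels.
* **All-zero expanded columns** scale by 1 instead of dividing by zero.
* Each level's block must have at least 2 rows; the fit refuses otherwise,
  naming the offending level.

## Neural-to-polynomial transition

A trained level is affine in its scaled expanded features. `extract_affine`
probes it with the zero vector (intercept) and the unit vectors (weights) —
a diagonal matrix of test signals — and verifies affineness on random
two-hot probes. Probing happens in the expanded space deliberately: probing
raw inputs would conflate monomials. Scaling is diagonal-linear, so weights
divide by the per-column scales, and each weight attaches to its monomial,
giving the level's polynomial in raw `(x, y_prev)`. Symbolic substitution
of each level's polynomial for the next level's `y_prev` (exact sparse
polynomial arithmetic, dict of exponent vectors) yields one polynomial in
the original inputs. Coefficients below `1e-12` in magnitude are dropped
from emitted polynomials (configurable via `COEFF_DROP_TOL`); `poly_degree`
uses the same threshold. Composition is refused above 6 input variables by
default — the term count at degree `2^L` is combinatorial, and the neural
form remains the practical representation there.

The equivalence `cascade_predict ≈ poly_eval(compose_polynomial)` holds to
~1e-14 relative on bounded inputs and is asserted at 1e-8 in the suite.

## Model selection and metrics

`compute_metrics` reports maximum residual error, MAE, MSE, and median
absolute error. `select_optimal_levels` implements the optimal-complexity
rule: the depth at the held-out error minimum (ties to the shallower
model), with an early-stop variant that halts at the first increase —
identical on unimodal profiles. `sweep_hidden_neurons` brute-forces a grid
of `m` values (grid entries beyond a level's expanded width clamp with a
warning) and selects by holdout MAE by default. `kfold_cv` reports
across-fold means and sample standard deviations.

## Synthetic data

`make_polynomial_dataset` draws features i.i.d. uniform on `[−1, 1]`
(bounded inputs keep quadratic expansions numerically tame and mirror
max-abs-scaled real data) and a generic polynomial with seeded standard
normal coefficients on *all* monomials up to the requested degree; the true
polynomial is returned with the sample, enabling recovery and degree-law
tests. `make_healthcare_like` emulates the *shape* of a physiological
monitoring table: 18 correlated bounded features (random-orthogonal
covariance with a fixed log-spaced spectrum, condition number ≈ 316),
driving a smooth sigmoidal target on a 55–185 beats/min scale with mildly
heteroscedastic noise. Neither generator reproduces any real dataset's
marginals or physiological semantics, so green tests demonstrate algorithmic
correctness and the qualitative depth/accuracy trade-off — not clinical
performance.

## Known limitations

* **A 2-level quadratic cascade does not span generic quartics.** The
  degree-4 part of the composed polynomial is `a·q₂²`, where `q₂` is the
  level-1 quadratic form — a 4-parameter cone inside the 5-dimensional
  space of binary quartic forms (it cannot even reach `x₁⁴ − x₂⁴`). Combined
  with greedy level-by-level training (each level is the least-squares fit
  of *its own* stage), exact recovery of an arbitrary degree-4 surface is
  impossible; on generic noiseless quartics the held-out error saturates
  around 15–25% of the target's spread, improving on a single level but not
  vanishing. Depth buys representable *families*, not all polynomials of
  the matching degree.
* Cascade levels are inherently sequential; there is nothing to
  parallelise across levels.
* Multi-output regression is supported structurally (`q > 1` pass-through
  in the SGTM) but the cascade chains a scalar prediction.
* Problem sizes in the test suite (hundreds to a few thousand rows) are
  chosen as compact, fully seeded benchmarks that exercise every code path;
  the algorithms themselves are vectorised and scale linearly in rows.
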