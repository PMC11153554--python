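"""Non-iterative neural-like structure trained by successive geometric transformations.

The model (SGTM: successive geometric transformations model) builds an
orthonormal basis of the training sample by a pivoted Gram-Schmidt sweep:
at every step the largest-norm residual row is taken as the *base vector*,
normalised, and projected out of every row.  The projection coefficients
``k`` play the role of hidden-layer signals of a feed-forward network whose
weights are found without any iterative optimisation.

Two modes are provided:

* **unsupervised** — decomposition of a feature matrix into principal-
  component-like coordinates plus the exact inverse (reconstruction);
* **supervised** — the same sweep on the column-augmented matrix
  ``[X | y]``; at prediction time the output components are unknown, so
  each hidden signal is estimated from the input part of the base
  direction alone and rescaled by a least-squares correction ``alpha``.

Both modes centre columns by their training means, so the intercept of the
fitted map is carried by the means rather than by an explicit bias term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, NotFittedError, ShapeError

__all__ = [
    "TransformStep",
    "SGTMModel",
    "fit_unsupervised",
    "fit_supervised",
    "transform",
    "reconstruct",
    "predict",
]

#: relative rank tolerance: stop creating steps once the best base norm falls
#: below this fraction of the largest initial row norm
RANK_TOLERANCE = 1e-10

#: minimum squared norm of the input part of a base direction for it to be
#: usable at prediction time (directions almost orthogonal to the input
#: subspace carry no information computable from inputs alone)
_INPUT_PART_TOL = 1e-12


@dataclass(frozen=True)
class TransformStep:
    """One geometric-transformation step.

    Attributes
    ----------
    step_index : int
        1-based position in the sweep.
    base_direction : (p + q,) ndarray
        Unit-norm direction of the selected base row (after centring).
    alpha : float
        Least-squares correction mapping the input-only hidden signal to
        the full one.  Zero / unused in unsupervised mode.
    base_row_index : int
        Training-row index the base was taken from.
    base_norm : float
        Euclidean norm of the residual base row before normalisation.
    """

    step_index: int
    base_direction: np.ndarray
    alpha: float
    base_row_index: int
    base_norm: float


@dataclass
class SGTMModel:
    """Ordered transformation steps plus centring statistics.

    ``m = len(steps)`` is the number of hidden neurons: steps are produced
    in descending base-norm order, so truncating the sequence keeps the
    most informative directions.
    """

    steps: list[TransformStep]
    input_means: np.ndarray
    output_means: np.ndarray
    p: int
    q: int
    _alphas: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self._alphas is None:
            self._alphas = np.array([s.alpha for s in self.steps], dtype=float)

    @property
    def m(self) -> int:
        return len(self.steps)

    @property
    def directions(self) -> np.ndarray:
        """(m, p + q) matrix of unit base directions."""
        if not self.steps:
            return np.zeros((0, self.p + self.q))
        return np.vstack([s.base_direction for s in self.steps])


def _validate_matrix(X, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError(f"{name} must be 2-D, got ndim={X.ndim}")
    if X.size == 0:
        raise InvalidInputError(f"{name} is empty")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return X


def _greedy_steps(Z: np.ndarray, max_steps: int, frobenius_stop: bool):
    """Pivoted Gram-Schmidt on rows of ``Z``; returns steps and final residual.

    Ties in the max-norm pivot go to the smallest row index (``argmax``
    returns the first maximum).  Steps whose base norm falls below the
    relative rank tolerance are never created.
    """
    R = Z.copy()
    init_row = float(np.max(np.linalg.norm(R, axis=1), initial=0.0))
    tol = RANK_TOLERANCE * init_row
    init_fro = float(np.linalg.norm(R))
    steps: list[TransformStep] = []
    for s in range(max_steps):
        if frobenius_stop and np.linalg.norm(R) <= RANK_TOLERANCE * init_fro:
            break
        norms = np.linalg.norm(R, axis=1)
        b = int(np.argmax(norms))
        bn = float(norms[b])
        if bn <= tol:
            break
        d = R[b] / bn
        k = R @ d
        R -= np.outer(k, d)
        steps.append(
            TransformStep(
                step_index=s + 1,
                base_direction=d,
                alpha=0.0,
                base_row_index=b,
                base_norm=bn,
            )
        )
    return steps, R


def _resolve_m(m, cap: int) -> int:
    if m == "full":
        return cap
    m = int(m)
    if m < 0:
        raise InvalidInputError(f"m must be >= 0, got {m}")
    return min(m, cap)


def fit_unsupervised(X, m="full", center: bool = True) -> SGTMModel:
    """Decompose a feature matrix by successive geometric transformations.

    Parameters
    ----------
    X : (N, p) array-like
        Training matrix.
    m : int or "full"
        Number of steps to retain.  ``"full"`` iterates until the residual
        Frobenius norm is negligible or ``p`` steps have been made.
    center : bool
        Subtract column means first (default).  With ``center=False`` the
        stored means are zero and the decomposition acts on raw rows.
    """
    X = _validate_matrix(X)
    p = X.shape[1]
    means = X.mean(axis=0) if center else np.zeros(p)
    steps, _ = _greedy_steps(X - means, _resolve_m(m, p), frobenius_stop=(m == "full"))
    return SGTMModel(steps=steps, input_means=means, output_means=np.zeros(0), p=p, q=0)


def _require_unsupervised(model: SGTMModel) -> None:
    if model.q != 0:
        raise InvalidInputError(
            "transform/reconstruct operate on unsupervised models (q = 0)"
        )


def transform(model: SGTMModel, X) -> np.ndarray:
    """Hidden-layer signals ``K`` (M x m) of each row of ``X``.

    Rows are centred by the training means, then projected step by step
    onto the stored unit base directions, the projection being removed
    after each step.
    """
    _require_unsupervised(model)
    X = _validate_matrix(X)
    if X.shape[1] != model.p:
        raise ShapeError(f"expected {model.p} columns, got {X.shape[1]}")
    R = X - model.input_means
    K = np.empty((X.shape[0], model.m))
    for s, step in enumerate(model.steps):
        d = step.base_direction
        k = R @ d
        K[:, s] = k
        R = R - np.outer(k, d)
    return K


def reconstruct(model: SGTMModel, K) -> np.ndarray:
    """Inverse transformation: rebuild rows from hidden signals.

    Exact (to floating point) for the training matrix when all steps were
    retained, because the base directions are orthonormal and span the
    centred row space.
    """
    _require_unsupervised(model)
    K = _validate_matrix(K, "K")
    if K.shape[1] != model.m:
        raise ShapeError(f"expected {model.m} columns, got {K.shape[1]}")
    return model.input_means + K @ model.directions


def _prediction_scores(D: np.ndarray, Xc: np.ndarray, p: int) -> np.ndarray:
    """Hidden signals computable from inputs alone.

    For each step the score is the exact projection coefficient of the
    current input residual on the input part of the base direction; that
    component is then removed so later steps see a deflated residual.
    Directions whose input part is (numerically) zero yield a zero score:
    nothing about them can be recovered from inputs.
    """
    n = Xc.shape[0]
    S = D.shape[0]
    K = np.zeros((n, S))
    r = Xc.copy()
    for s in range(S):
        din = D[s, :p]
        nin = float(din @ din)
        if nin <= _INPUT_PART_TOL:
            continue
        k = (r @ din) / nin
        K[:, s] = k
        r = r - np.outer(k, din)
    return K


def fit_supervised(X, y, m="full") -> SGTMModel:
    """Fit the regression mode on the column-augmented matrix ``[X | y]``.

    The sweep itself is the unsupervised procedure run on the centred
    augmented rows, using exact full-vector projection coefficients (this
    is what makes the base directions orthonormal).  Afterwards the
    correction coefficients ``alpha`` are fitted by least squares: the
    hidden signals that prediction will actually compute (input parts
    only) are regressed jointly onto the training outputs, so that at full
    rank the fitted map reproduces the ordinary least-squares solution.

    A zero-variance augmented matrix yields a model with zero steps, i.e.
    the mean predictor.
    """
    X = _validate_matrix(X)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    y = _validate_matrix(y, "y")
    if y.shape[0] != X.shape[0]:
        raise ShapeError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    if X.shape[0] < 2:
        raise InvalidInputError("supervised fitting needs at least 2 rows")
    p, q = X.shape[1], y.shape[1]
    xm = X.mean(axis=0)
    ym = y.mean(axis=0)
    Z = np.hstack([X - xm, y - ym])
    steps, _ = _greedy_steps(Z, _resolve_m(m, p + q), frobenius_stop=(m == "full"))

    if steps:
        D = np.vstack([s.base_direction for s in steps])
        Kin = _prediction_scores(D, X - xm, p)
        # one regression feature per (step, output): Kin[:, s] * d_out[s, j]
        Dout = D[:, p:]
        G = np.vstack([Kin * Dout[:, j][None, :] for j in range(q)])
        t = (y - ym).T.ravel()
        alphas, *_ = np.linalg.lstsq(G, t, rcond=None)
        steps = [
            TransformStep(
                step_index=s.step_index,
                base_direction=s.base_direction,
                alpha=float(a),
                base_row_index=s.base_row_index,
                base_norm=s.base_norm,
            )
            for s, a in zip(steps, alphas)
        ]

    return SGTMModel(steps=steps, input_means=xm, output_means=ym, p=p, q=q)


def predict(model: SGTMModel, X) -> np.ndarray:
    """Predict outputs for rows of ``X`` (returns an (M, q) matrix).

    Mirrors the training-time score computation: centre the input, take
    the exact projection coefficient on each step's input part, rescale
    it by the step's ``alpha``, and accumulate the step's output part.
    The column means of the training outputs are added back at the end.
    """
    if model.q < 1:
        raise NotFittedError("predict requires a supervised model (q >= 1)")
    X = _validate_matrix(X)
    if X.shape[1] != model.p:
        raise ShapeError(f"expected {model.p} columns, got {X.shape[1]}")
    out = np.tile(model.output_means, (X.shape[0], 1))
    if model.m == 0:
        return out
    D = model.directions
    Kin = _prediction_scores(D, X - model.input_means, model.p)
    out += (Kin * model._alphas[None, :]) @ D[:, model.p :]
    return out
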