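"""Transition from the neural form to an explicit polynomial model.

Each trained cascade level is *affine* in its scaled expanded features, so
its coefficients can be read off by probing with a diagonal matrix of test
signals: the zero vector gives the intercept, each unit vector gives one
weight.  Folding the (linear) max-abs scaling into those weights and
attaching them to the level's monomial basis yields an explicit polynomial
of the expansion degree in the raw variables (plus the chained attribute
``y_prev`` at levels > 1).  Substituting each level's polynomial for
``y_prev`` in the next one produces a single polynomial in the original
inputs whose degree doubles per level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import AUGMENT_NAME, CascadeModel
from .errors import (
    InvalidInputError,
    NotAffineError,
    NotFittedError,
    ShapeError,
)
from .sgtm import predict as sgtm_predict

__all__ = [
    "Polynomial",
    "poly_eval",
    "poly_degree",
    "extract_affine",
    "level_polynomial",
    "compose_polynomial",
    "polynomial_table",
    "polynomial_text",
]

#: coefficients with smaller absolute value are dropped from emitted polynomials
COEFF_DROP_TOL = 1e-12


@dataclass(frozen=True)
class Polynomial:
    """Sparse multivariate polynomial: exponent vector -> coefficient.

    Exponent vectors are tuples of non-negative integers, one entry per
    variable in ``variable_names``; the zero vector holds the intercept.
    """

    variable_names: tuple[str, ...]
    coefficients: dict[tuple[int, ...], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.variable_names)
        for exp in self.coefficients:
            if len(exp) != n or any(e < 0 for e in exp):
                raise InvalidInputError(f"bad exponent vector {exp} for {n} variables")


def _zero_exp(n: int) -> tuple[int, ...]:
    return (0,) * n


def poly_eval(P: Polynomial, x) -> float:
    """Direct monomial-sum evaluation at one point."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != len(P.variable_names):
        raise ShapeError(
            f"point has {x.shape[0]} coordinates, polynomial has "
            f"{len(P.variable_names)} variables"
        )
    total = 0.0
    for exp, c in P.coefficients.items():
        term = c
        for v, e in zip(x, exp):
            if e:
                term *= v**e
        total += term
    return float(total)


def poly_eval_many(P: Polynomial, X) -> np.ndarray:
    """Vectorised evaluation over rows of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(P.variable_names):
        raise ShapeError("column count does not match the polynomial's variables")
    out = np.zeros(X.shape[0])
    for exp, c in P.coefficients.items():
        term = np.full(X.shape[0], c)
        for v, e in enumerate(exp):
            if e:
                term *= X[:, v] ** e
        out += term
    return out


def poly_degree(P: Polynomial, tol: float = COEFF_DROP_TOL) -> int:
    """Maximum total degree over terms with non-negligible coefficients."""
    degs = [sum(exp) for exp, c in P.coefficients.items() if abs(c) > tol]
    return max(degs, default=0)


def _poly_add(a: dict, b: dict, scale: float = 1.0) -> dict:
    out = dict(a)
    for exp, c in b.items():
        out[exp] = out.get(exp, 0.0) + scale * c
    return out


def _poly_mul(a: dict, b: dict) -> dict:
    out: dict[tuple[int, ...], float] = {}
    for ea, ca in a.items():
        for eb, cb in b.items():
            e = tuple(x + y for x, y in zip(ea, eb))
            out[e] = out.get(e, 0.0) + ca * cb
    return out


def _poly_pow(a: dict, k: int, n_vars: int) -> dict:
    out = {_zero_exp(n_vars): 1.0}
    for _ in range(k):
        out = _poly_mul(out, a)
    return out


def _clean(coeffs: dict, tol: float = COEFF_DROP_TOL) -> dict:
    return {e: c for e, c in coeffs.items() if abs(c) > tol}


def substitute(P: Polynomial, var: str, Q: Polynomial) -> Polynomial:
    """Exact substitution of polynomial ``Q`` for variable ``var`` of ``P``.

    ``Q`` must be a polynomial over exactly the remaining variables of
    ``P`` (in the same order); the result is over those variables.
    """
    if var not in P.variable_names:
        raise InvalidInputError(f"{var!r} is not a variable of the polynomial")
    vi = P.variable_names.index(var)
    rest = tuple(n for n in P.variable_names if n != var)
    if Q.variable_names != rest:
        raise InvalidInputError(
            "substituted polynomial must be over the remaining variables "
            f"{rest}, got {Q.variable_names}"
        )
    n = len(rest)
    out: dict[tuple[int, ...], float] = {}
    pow_cache: dict[int, dict] = {0: {_zero_exp(n): 1.0}}
    for exp, c in P.coefficients.items():
        k = exp[vi]
        base = {tuple(e for i, e in enumerate(exp) if i != vi): c}
        if k not in pow_cache:
            pow_cache[k] = _poly_pow(Q.coefficients, k, n)
        out = _poly_add(out, _poly_mul(base, pow_cache[k]))
    return Polynomial(variable_names=rest, coefficients=_clean(out))


def extract_affine(predictor, d: int, n_checks: int = 5, tol: float = 1e-8, seed: int = 0):
    """Read intercept and weights of an affine map by diagonal test signals.

    ``predictor`` maps a length-``d`` vector to a scalar.  The intercept
    is its value at the origin; weight ``j`` is the response to the j-th
    unit vector minus the intercept.  Affineness is verified on random
    two-hot probes; a violation raises :class:`NotAffineError`.
    """
    d = int(d)
    if d < 1:
        raise InvalidInputError(f"d must be >= 1, got {d}")
    intercept = float(predictor(np.zeros(d)))
    weights = np.empty(d)
    eye = np.eye(d)
    for j in range(d):
        weights[j] = float(predictor(eye[j])) - intercept
    rng = np.random.default_rng(seed)
    ref = max(1.0, abs(intercept), float(np.max(np.abs(weights))))
    for _ in range(n_checks):
        j, k = rng.integers(0, d, size=2)
        got = float(predictor(eye[j] + eye[k]))
        want = intercept + weights[j] + weights[k]
        if abs(got - want) > tol * ref:
            raise NotAffineError(
                f"predictor is not affine: probe e_{j}+e_{k} gave {got}, "
                f"expected {want}"
            )
    return intercept, weights


def _check_fitted(model: CascadeModel, level: int) -> None:
    if not model.levels:
        raise NotFittedError("cascade model has no trained levels")
    if not 1 <= level <= model.n_levels:
        raise InvalidInputError(f"level must be in [1, {model.n_levels}], got {level}")


def level_polynomial(model: CascadeModel, level: int) -> Polynomial:
    """Explicit polynomial of one level in raw ``(x, y_prev)`` variables.

    The level's SGTM is probed in its scaled expanded feature space, the
    max-abs scaling is folded into the weights, and each weight is
    attached to its monomial, giving a degree-``config.degree`` polynomial
    whose evaluation equals the level's raw prediction map.
    """
    _check_fitted(model, level)
    lvl = model.levels[level - 1]
    width = len(lvl.basis)

    def predictor(z: np.ndarray) -> float:
        return float(sgtm_predict(lvl.sgtm, z[None, :])[0, 0])

    intercept, weights = extract_affine(predictor, width)
    names = lvl.basis.variable_names
    coeffs: dict[tuple[int, ...], float] = {_zero_exp(len(names)): intercept}
    for j, exp in enumerate(lvl.basis.exponents):
        coeffs[exp] = coeffs.get(exp, 0.0) + weights[j] / lvl.scaler.scale[j]
    return Polynomial(variable_names=names, coefficients=_clean(coeffs))


def compose_polynomial(model: CascadeModel, max_inputs: int = 6) -> Polynomial:
    """Single polynomial of the whole cascade in the original variables.

    Substitutes level ``l-1``'s composed polynomial for ``y_prev`` inside
    level ``l``'s polynomial, level by level.  The term count explodes
    combinatorially with the input dimension (the degree doubles per
    level), so the operation refuses to run above ``max_inputs`` features.
    """
    if not model.levels:
        raise NotFittedError("cascade model has no trained levels")
    if model.n_features > max_inputs:
        raise InvalidInputError(
            f"symbolic composition with {model.n_features} inputs exceeds the cap "
            f"({max_inputs}); use the neural form (cascade_predict) instead"
        )
    composed = level_polynomial(model, 1)
    for ell in range(2, model.n_levels + 1):
        composed = substitute(level_polynomial(model, ell), AUGMENT_NAME, composed)
    return composed


def polynomial_table(P: Polynomial) -> pd.DataFrame:
    """One row per monomial: exponent columns plus the coefficient."""
    rows = sorted(P.coefficients.items(), key=lambda t: (sum(t[0]), tuple(-e for e in t[0])))
    data = {name: [exp[i] for exp, _ in rows] for i, name in enumerate(P.variable_names)}
    data["coefficient"] = [c for _, c in rows]
    return pd.DataFrame(data)


def polynomial_text(P: Polynomial, precision: int = 6) -> str:
    """Human-readable formula, constant first, then ascending degree."""
    parts = []
    for exp, c in sorted(
        P.coefficients.items(), key=lambda t: (sum(t[0]), tuple(-e for e in t[0]))
    ):
        mono = "*".join(
            name if e == 1 else f"{name}^{e}"
            for name, e in zip(P.variable_names, exp)
            if e
        )
        coef = f"{c:+.{precision}g}"
        parts.append(coef if not mono else f"{coef}*{mono}")
    return " ".join(parts) if parts else "0"
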