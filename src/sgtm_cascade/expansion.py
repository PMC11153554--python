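"""Kolmogorov-Gabor polynomial feature expansion.

The expansion maps ``n`` inputs to the values of all monomials of total
degree 1..k (no constant column: the intercept is handled by centring in
the regression stage).  For the default ``k = 2`` the number of expanded
columns is ``n + n(n+1)/2``.

The monomial ordering is canonical and frozen so that serialised models
are portable: ascending total degree, then graded-lexicographic (the
exponent of the first variable decreases last), which puts the original
variables first, in their input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from math import comb

import numpy as np

from .errors import InvalidInputError

__all__ = ["MonomialBasis", "kg_term_count", "kg_terms", "kg_expand"]


def kg_term_count(n: int, degree: int) -> int:
    """Number of monomials of total degree 1..degree in ``n`` variables.

    Equals ``C(n + degree, degree) - 1``; for ``degree = 2`` this is
    ``n + n(n+1)/2``.
    """
    n, degree = int(n), int(degree)
    if n < 1 or degree < 1:
        raise InvalidInputError(f"need n >= 1 and degree >= 1, got n={n}, degree={degree}")
    return comb(n + degree, degree) - 1


@dataclass(frozen=True)
class MonomialBasis:
    """Ordered monomial exponent vectors over named variables."""

    variable_names: tuple[str, ...]
    degree: int
    exponents: tuple[tuple[int, ...], ...]

    def __len__(self) -> int:
        return len(self.exponents)

    def term_names(self) -> list[str]:
        """Human-readable monomial labels, e.g. ``x1^2*x2``."""
        out = []
        for exp in self.exponents:
            parts = []
            for name, e in zip(self.variable_names, exp):
                if e == 1:
                    parts.append(name)
                elif e > 1:
                    parts.append(f"{name}^{e}")
            out.append("*".join(parts))
        return out


def kg_terms(variable_names, degree: int) -> MonomialBasis:
    """Build the canonical monomial basis over the given variables."""
    names = tuple(str(n) for n in variable_names)
    if not names:
        raise InvalidInputError("variable_names is empty")
    if len(set(names)) != len(names):
        raise InvalidInputError("variable_names contains duplicates")
    degree = int(degree)
    if degree < 1:
        raise InvalidInputError(f"degree must be >= 1, got {degree}")
    n = len(names)
    exps = []
    for d in range(1, degree + 1):
        for combo in combinations_with_replacement(range(n), d):
            e = [0] * n
            for j in combo:
                e[j] += 1
            exps.append(tuple(e))
    basis = MonomialBasis(variable_names=names, degree=degree, exponents=tuple(exps))
    assert len(basis) == kg_term_count(n, degree)
    return basis


def kg_expand(X, degree: int, basis: MonomialBasis | None = None) -> np.ndarray:
    """Evaluate the monomial basis on every row of ``X``.

    The first ``n`` output columns equal ``X`` itself.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        raise InvalidInputError("X is empty")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("X contains non-finite values")
    n = X.shape[1]
    if basis is None:
        basis = kg_terms([f"x{j + 1}" for j in range(n)], degree)
    if len(basis.variable_names) != n:
        raise InvalidInputError(
            f"basis over {len(basis.variable_names)} variables, X has {n} columns"
        )
    out = np.empty((X.shape[0], len(basis)))
    for j, exp in enumerate(basis.exponents):
        col = np.ones(X.shape[0])
        for v, e in enumerate(exp):
            if e == 1:
                col = col * X[:, v]
            elif e > 1:
                col = col * X[:, v] ** e
        out[:, j] = col
    return out
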