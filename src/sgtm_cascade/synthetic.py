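"""Seeded synthetic-data generators.

Two families are provided.  ``make_polynomial_dataset`` draws exact
polynomial response surfaces of known degree — the workhorse of
parameter-recovery and degree-law tests, since the true model is returned
alongside the sample.  ``make_healthcare_like`` emulates the *shape* of a
physiological tabular regression problem: 18 correlated bounded features
driving a smooth nonlinear, positive, bounded target (a heart-rate-like
scale) with mildly heteroscedastic noise.  Neither generator attempts to
reproduce any real dataset's marginals; they provide data with the
structural properties the method assumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset
from .errors import InvalidInputError
from .expansion import kg_terms
from .interpret import Polynomial, poly_eval_many

__all__ = ["SyntheticSpec", "make_polynomial_dataset", "make_healthcare_like"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a seeded synthetic regression sample.

    ``coefficient_scale`` is the standard deviation of the seeded normal
    draws used for the true polynomial's coefficients; features are i.i.d.
    uniform on [-1, 1] so that quadratic expansion stays numerically tame
    (mirroring max-abs-scaled real data).
    """

    n_samples: int = 1000
    n_features: int = 2
    target_kind: str = "polynomial"
    degree: int = 2
    noise_sd: float = 0.0
    seed: int = 0
    coefficient_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise InvalidInputError("n_samples must be >= 2")
        if self.n_features < 1:
            raise InvalidInputError("n_features must be >= 1")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.degree < 1:
            raise InvalidInputError("degree must be >= 1")
        if self.target_kind not in ("linear", "polynomial", "smooth-nonlinear"):
            raise InvalidInputError(f"unknown target_kind {self.target_kind!r}")


def make_polynomial_dataset(spec: SyntheticSpec):
    """Exact polynomial surface plus optional Gaussian noise.

    Returns ``(dataset, true_polynomial)``.  All monomials up to
    ``spec.degree`` (including the intercept) receive seeded normal
    coefficients; ``target_kind="linear"`` is the degree-1 special case.
    """
    if spec.target_kind not in ("polynomial", "linear"):
        raise InvalidInputError(
            f"make_polynomial_dataset needs a polynomial-type spec, got "
            f"{spec.target_kind!r}"
        )
    degree = 1 if spec.target_kind == "linear" else spec.degree
    rng = np.random.default_rng(spec.seed)
    names = tuple(f"x{j + 1}" for j in range(spec.n_features))
    X = rng.uniform(-1.0, 1.0, size=(spec.n_samples, spec.n_features))
    basis = kg_terms(names, degree)
    coeffs = {(0,) * spec.n_features: float(rng.normal(0.0, spec.coefficient_scale))}
    for exp in basis.exponents:
        coeffs[exp] = float(rng.normal(0.0, spec.coefficient_scale))
    truth = Polynomial(variable_names=names, coefficients=coeffs)
    y = poly_eval_many(truth, X)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
    return Dataset(X=X, y=y, feature_names=names, target_name="y"), truth


def make_healthcare_like(n_samples: int, seed: int = 0) -> Dataset:
    """18 correlated features with a smooth bounded positive target.

    Features are a random-covariance Gaussian (condition number of the
    covariance kept at ~316, well under 1e3) squashed through ``tanh`` to
    a bounded range.  The target sits on a resting-to-exercise heart-rate
    scale: 55-185 beats/min, a smooth nonlinear function of a few feature
    combinations, plus heteroscedastic noise that grows with the first
    feature's magnitude.
    """
    n_samples = int(n_samples)
    if n_samples < 10:
        raise InvalidInputError("n_samples must be >= 10")
    rng = np.random.default_rng(seed)
    p = 18
    # random orthogonal factor times a fixed decaying spectrum
    Q, _ = np.linalg.qr(rng.normal(size=(p, p)))
    spectrum = np.logspace(0.0, -2.5, p)  # condition number 10^2.5
    C = (Q * spectrum) @ Q.T
    Z = rng.multivariate_normal(np.zeros(p), C, size=n_samples)
    X = np.tanh(Z / np.sqrt(np.diag(C)))  # bounded, correlation preserved in shape
    w1, w2 = rng.normal(size=p), rng.normal(size=p)
    u1, u2 = X @ w1, X @ w2
    drive = 1.0 / (1.0 + np.exp(-(u1 + 0.5 * u2**2 - 0.3 * u1 * u2)))
    noise = rng.normal(size=n_samples) * (1.0 + 1.5 * np.abs(X[:, 0]))
    y = 55.0 + 130.0 * drive + noise
    names = tuple(f"feature_{j + 1:02d}" for j in range(p))
    return Dataset(X=X, y=y, feature_names=names, target_name="heart_rate")
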