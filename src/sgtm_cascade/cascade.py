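"""Cascade ensemble of SGTM levels with chained predicted-output augmentation.

The training set is partitioned into ``L`` disjoint blocks, one per level.
Level 1 regresses the target on the quadratic (by default) Kolmogorov-Gabor
expansion of its block.  Every later level first pushes its own block
through the already-trained levels to obtain the previous level's
prediction, appends that single value as an extra attribute ``y_prev``,
expands the augmented vector, and fits a fresh SGTM against the block's
true targets.  Application mode repeats the same chain on new rows.

Because each level is affine in its expanded features, the composition is
a polynomial in the original inputs whose degree doubles per level
(``2^L`` for quadratic expansions) — the response-surface-linearisation
principle: each stage stays linear to fit, yet the chain represents
high-degree surfaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import Dataset
from .errors import InvalidConfigError, InvalidInputError, NotFittedError, ShapeError
from .expansion import MonomialBasis, kg_expand, kg_term_count, kg_terms
from .preprocess import MaxAbsScaler, apply_maxabs, fit_maxabs, partition_levels
from .sgtm import SGTMModel, fit_supervised, predict

__all__ = [
    "CascadeConfig",
    "LevelModel",
    "CascadeModel",
    "fit_cascade",
    "cascade_augment",
    "cascade_predict",
    "AUGMENT_NAME",
]

#: name of the chained-prediction attribute appended at levels > 1
AUGMENT_NAME = "y_prev"


@dataclass(frozen=True)
class CascadeConfig:
    """Hyperparameters of the cascade.

    ``hidden_neurons`` is the per-level number of retained SGTM steps,
    shared across levels; ``"full"`` keeps every step.  Values exceeding a
    level's expanded input width are clamped with a warning.
    """

    levels: int = 3
    degree: int = 2
    hidden_neurons: int | str = "full"
    seed: int = 0
    shuffled_partition: bool = True

    def __post_init__(self) -> None:
        if int(self.levels) < 1:
            raise InvalidConfigError(f"levels must be >= 1, got {self.levels}")
        if int(self.degree) < 1:
            raise InvalidConfigError(f"degree must be >= 1, got {self.degree}")
        if self.hidden_neurons != "full" and int(self.hidden_neurons) < 0:
            raise InvalidConfigError("hidden_neurons must be >= 0 or 'full'")


@dataclass
class LevelModel:
    scaler: MaxAbsScaler
    sgtm: SGTMModel
    basis: MonomialBasis


@dataclass
class CascadeModel:
    config: CascadeConfig
    levels: list[LevelModel] = field(default_factory=list)
    feature_names: tuple[str, ...] = ()
    target_name: str = "y"

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def _resolve_hidden(config: CascadeConfig, width: int):
    m = config.hidden_neurons
    if m == "full":
        return "full"
    m = int(m)
    cap = width + 1  # expanded inputs + one output column
    if m > cap:
        warnings.warn(
            f"hidden_neurons={m} exceeds the expanded input width; clamped to {cap}",
            stacklevel=3,
        )
        return cap
    return m


def fit_cascade(train: Dataset, config: CascadeConfig) -> CascadeModel:
    """Train the full chain on a partitioned training set."""
    if train.y is None:
        raise InvalidInputError("training dataset has no target column")
    L = int(config.levels)
    if L > train.n_samples:
        raise InvalidConfigError(
            f"levels={L} exceeds the number of training rows ({train.n_samples})"
        )
    plan = partition_levels(train, L, seed=config.seed, shuffled=config.shuffled_partition)
    for ell, idx in enumerate(plan.level_row_indices, start=1):
        if idx.size < 2:
            raise InvalidConfigError(
                f"level {ell} training block has {idx.size} row(s); need at least 2"
            )

    model = CascadeModel(
        config=config, feature_names=train.feature_names, target_name=train.target_name
    )
    for ell, idx in enumerate(plan.level_row_indices, start=1):
        Xb, yb = train.X[idx], train.y[idx]
        if ell == 1:
            names = list(train.feature_names)
            base = Xb
        else:
            names = list(train.feature_names) + [AUGMENT_NAME]
            y_prev = cascade_augment(model, Xb, upto_level=ell - 1)
            base = np.column_stack([Xb, y_prev])
        basis = kg_terms(names, config.degree)
        phi = kg_expand(base, config.degree, basis=basis)
        scaler = fit_maxabs(phi)
        sgtm = fit_supervised(
            apply_maxabs(scaler, phi), yb, m=_resolve_hidden(config, phi.shape[1])
        )
        model.levels.append(LevelModel(scaler=scaler, sgtm=sgtm, basis=basis))
    return model


def cascade_augment(model: CascadeModel, X, upto_level: int) -> np.ndarray:
    """Chained prediction of levels 1..upto_level for rows of ``X``."""
    if not model.levels:
        raise NotFittedError("cascade model has no trained levels")
    if not 1 <= upto_level <= model.n_levels:
        raise InvalidInputError(
            f"upto_level must be in [1, {model.n_levels}], got {upto_level}"
        )
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ShapeError(f"expected {model.n_features} columns, got {X.shape[1]}")
    y_hat = None
    for ell in range(1, upto_level + 1):
        lvl = model.levels[ell - 1]
        base = X if ell == 1 else np.column_stack([X, y_hat])
        phi = kg_expand(base, lvl.basis.degree, basis=lvl.basis)
        y_hat = predict(lvl.sgtm, apply_maxabs(lvl.scaler, phi))[:, 0]
    return y_hat


def cascade_predict(model: CascadeModel, X) -> np.ndarray:
    """Final-level prediction (the cascade's output)."""
    return cascade_augment(model, X, upto_level=model.n_levels)
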