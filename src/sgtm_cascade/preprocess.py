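"""Scaling, train/test splitting, and level partitioning.

Each cascade level normalises its (expanded) training block with max-abs
scaling — per-column division by the largest absolute value seen at fit
time — which maps training columns into [-1, 1] without shifting zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .data import Dataset
from .errors import InvalidInputError, ShapeError

__all__ = [
    "MaxAbsScaler",
    "PartitionPlan",
    "fit_maxabs",
    "apply_maxabs",
    "split_train_test",
    "partition_levels",
]


@dataclass(frozen=True)
class MaxAbsScaler:
    """Per-column maximum absolute values; all-zero columns scale by 1."""

    scale: np.ndarray


def fit_maxabs(X) -> MaxAbsScaler:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise InvalidInputError("fit_maxabs needs a non-empty 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("X contains non-finite values")
    scale = np.max(np.abs(X), axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    return MaxAbsScaler(scale=scale)


def apply_maxabs(scaler: MaxAbsScaler, X, invert: bool = False) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    one_d = X.ndim == 1
    if one_d:
        X = X[None, :]
    if X.shape[1] != scaler.scale.shape[0]:
        raise ShapeError(
            f"scaler fitted on {scaler.scale.shape[0]} columns, got {X.shape[1]}"
        )
    out = X * scaler.scale if invert else X / scaler.scale
    return out[0] if one_d else out


def split_train_test(dataset: Dataset, test_fraction: float = 0.30, seed: int = 0):
    """Seeded uniform shuffle, then split; train gets ``ceil((1 - f) N)`` rows."""
    if not 0.0 < test_fraction < 1.0:
        raise InvalidInputError(f"test_fraction must be in (0, 1), got {test_fraction}")
    n = dataset.n_samples
    if n < 2:
        raise InvalidInputError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = ceil((1.0 - test_fraction) * n)
    return dataset.subset(order[:n_train]), dataset.subset(order[n_train:])


@dataclass(frozen=True)
class PartitionPlan:
    """Disjoint near-equal row blocks, one per cascade level."""

    level_row_indices: tuple[np.ndarray, ...]
    seed: int
    shuffled: bool

    @property
    def n_levels(self) -> int:
        return len(self.level_row_indices)


def partition_levels(
    train_dataset: Dataset, L: int, seed: int = 0, shuffled: bool = True
) -> PartitionPlan:
    """Partition training rows into ``L`` blocks of near-equal size.

    After an optional seeded shuffle the rows are cut into contiguous
    blocks; the first ``N mod L`` blocks receive one extra row.
    """
    L = int(L)
    n = train_dataset.n_samples
    if L < 1:
        raise InvalidInputError(f"L must be >= 1, got {L}")
    if L > n:
        raise InvalidInputError(f"cannot make {L} blocks from {n} rows")
    order = np.arange(n)
    if shuffled:
        order = np.random.default_rng(seed).permutation(n)
    base, extra = divmod(n, L)
    blocks = []
    start = 0
    for ell in range(L):
        size = base + (1 if ell < extra else 0)
        blocks.append(order[start : start + size])
        start += size
    return PartitionPlan(level_row_indices=tuple(blocks), seed=seed, shuffled=shuffled)
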