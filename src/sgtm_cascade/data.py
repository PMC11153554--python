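"""Tabular dataset container used by every pipeline stage.

A :class:`Dataset` is a plain feature matrix plus an optional target vector
with column names attached.  It is deliberately thin: heavy lifting (CSV
parsing, validation of raw files) lives in :mod:`sgtm_cascade.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = ["Dataset"]


def _as_float_matrix(X, name: str) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise InvalidInputError(f"{name} must be a 2-D matrix, got ndim={arr.ndim}")
    if arr.size == 0:
        raise InvalidInputError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


@dataclass
class Dataset:
    """Feature matrix, optional target vector, and column names.

    Parameters
    ----------
    X : (N, p) ndarray
        Feature matrix; must be finite.
    y : (N,) ndarray, optional
        Target vector.  ``None`` for predict-only data.
    feature_names : sequence of str, optional
        Unique column names; defaults to ``x1..xp``.
    target_name : str
        Name of the target column (default ``"y"``).
    """

    X: np.ndarray
    y: np.ndarray | None = None
    feature_names: tuple[str, ...] = field(default=())
    target_name: str = "y"

    def __post_init__(self) -> None:
        self.X = _as_float_matrix(self.X, "X")
        if self.y is not None:
            y = np.asarray(self.y, dtype=float).ravel()
            if y.shape[0] != self.X.shape[0]:
                raise InvalidInputError(
                    f"target length {y.shape[0]} != number of rows {self.X.shape[0]}"
                )
            if not np.all(np.isfinite(y)):
                raise InvalidInputError("target contains non-finite values")
            self.y = y
        if not self.feature_names:
            self.feature_names = tuple(f"x{j + 1}" for j in range(self.X.shape[1]))
        else:
            self.feature_names = tuple(str(n) for n in self.feature_names)
        if len(self.feature_names) != self.X.shape[1]:
            raise InvalidInputError(
                f"{len(self.feature_names)} feature names for {self.X.shape[1]} columns"
            )
        names = self.feature_names + (self.target_name,)
        if len(set(names)) != len(names):
            raise InvalidInputError("column names must be unique")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, indices) -> "Dataset":
        """Row-subset view (copies data)."""
        idx = np.asarray(indices, dtype=int)
        return Dataset(
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
            feature_names=self.feature_names,
            target_name=self.target_name,
        )

    def to_frame(self) -> pd.DataFrame:
        """Materialise as a pandas DataFrame (target last, when present)."""
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        if self.y is not None:
            df[self.target_name] = self.y
        return df
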