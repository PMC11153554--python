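"""Error metrics, optimal cascade-depth selection, hidden-neuron sweep, CV.

Model selection follows the optimal-complexity principle: grow the cascade
while the held-out error decreases and stop at its minimum — deeper chains
keep improving the training fit but eventually lose generalisation as the
per-level blocks shrink and the composed degree explodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade import CascadeConfig, CascadeModel, cascade_predict, fit_cascade
from .data import Dataset
from .errors import InvalidInputError

__all__ = [
    "MetricReport",
    "compute_metrics",
    "select_optimal_levels",
    "sweep_hidden_neurons",
    "kfold_cv",
]

METRIC_NAMES = ("mre", "mae", "mse", "medae")


@dataclass(frozen=True)
class MetricReport:
    """Maximum residual, mean absolute, mean squared, median absolute error."""

    mre: float
    mae: float
    mse: float
    medae: float
    n: int

    def as_dict(self) -> dict:
        return {"mre": self.mre, "mae": self.mae, "mse": self.mse,
                "medae": self.medae, "n": self.n}


def compute_metrics(y_true, y_pred) -> MetricReport:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0:
        raise InvalidInputError("empty input")
    if y_true.shape != y_pred.shape:
        raise InvalidInputError(
            f"length mismatch: {y_true.shape[0]} vs {y_pred.shape[0]}"
        )
    r = np.abs(y_true - y_pred)
    return MetricReport(
        mre=float(np.max(r)),
        mae=float(np.mean(r)),
        mse=float(np.mean(r**2)),
        medae=float(np.median(r)),
        n=int(y_true.size),
    )


def select_optimal_levels(per_level_test_errors, mode: str = "argmin") -> int:
    """Pick the cascade depth at the held-out error minimum.

    ``mode="argmin"`` scans the whole sequence (ties go to the smallest
    depth).  ``mode="early_stop"`` stops at the first increase and returns
    the previous depth — equivalent on unimodal sequences.
    """
    errors = np.asarray(per_level_test_errors, dtype=float)
    if errors.size == 0:
        raise InvalidInputError("empty error sequence")
    if np.any(errors <= 0) or not np.all(np.isfinite(errors)):
        raise InvalidInputError("errors must be positive finite numbers")
    if mode == "argmin":
        return int(np.argmin(errors)) + 1
    if mode == "early_stop":
        for i in range(1, errors.size):
            if errors[i] > errors[i - 1]:
                return i
        return int(errors.size)
    raise InvalidInputError(f"unknown mode {mode!r}")


def _holdout_metric(report: MetricReport, criterion: str) -> float:
    if criterion not in METRIC_NAMES:
        raise InvalidInputError(f"criterion must be one of {METRIC_NAMES}")
    return getattr(report, criterion)


def sweep_hidden_neurons(
    train: Dataset,
    holdout: Dataset,
    config: CascadeConfig,
    m_grid,
    criterion: str = "mae",
):
    """Brute-force sweep of the retained-step count ``m``.

    Fits one cascade per grid value (grid values above a level's expanded
    width are clamped inside the fit, with a warning) and evaluates on the
    holdout set.  Returns ``(table, m_star)`` where ``table`` is a list of
    ``(m, MetricReport)`` pairs and ``m_star`` minimises the holdout
    criterion (ties to the smaller ``m``).
    """
    m_grid = [int(m) for m in m_grid]
    if not m_grid:
        raise InvalidInputError("empty m grid")
    if holdout.y is None:
        raise InvalidInputError("holdout dataset has no target")
    table = []
    for m in m_grid:
        cfg = CascadeConfig(
            levels=config.levels,
            degree=config.degree,
            hidden_neurons=m,
            seed=config.seed,
            shuffled_partition=config.shuffled_partition,
        )
        model = fit_cascade(train, cfg)
        report = compute_metrics(holdout.y, cascade_predict(model, holdout.X))
        table.append((m, report))
    best = min(table, key=lambda t: (_holdout_metric(t[1], criterion), t[0]))
    return table, best[0]


def kfold_cv(dataset: Dataset, config: CascadeConfig, k: int = 5, seed: int = 0):
    """Seeded k-fold cross-validation of the cascade.

    Returns a dict ``metric -> (mean, sd)`` with the across-fold sample
    standard deviation (zero when a single fold value exists).
    """
    k = int(k)
    n = dataset.n_samples
    if dataset.y is None:
        raise InvalidInputError("dataset has no target")
    if k < 2:
        raise InvalidInputError(f"k must be >= 2, got {k}")
    if k > n:
        raise InvalidInputError(f"k={k} exceeds the number of rows ({n})")
    order = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(order, k)
    per_fold = {name: [] for name in METRIC_NAMES}
    for i in range(k):
        test_idx = folds[i]
        train_idx = np.concatenate([folds[j] for j in range(k) if j != i])
        model = fit_cascade(dataset.subset(train_idx), config)
        report = compute_metrics(
            dataset.y[test_idx], cascade_predict(model, dataset.X[test_idx])
        )
        for name in METRIC_NAMES:
            per_fold[name].append(getattr(report, name))
    out = {}
    for name, vals in per_fold.items():
        vals = np.asarray(vals)
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out[name] = (float(np.mean(vals)), sd)
    return out
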