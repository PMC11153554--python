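"""CSV dataset I/O and the JSON model archive.

CSV dialect: comma separator, ``.`` decimal, UTF-8, header row required.
Values are written in scientific notation with 17 significant digits so a
write/read round trip is value-exact for float64.

The model archive is human-readable structured JSON rather than a binary
pickle — a deliberate choice for a method whose selling point is that the
fitted model can be inspected (and exported) as an explicit polynomial.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cascade import CascadeConfig, CascadeModel, LevelModel
from .data import Dataset
from .errors import ArchiveError, InvalidInputError
from .expansion import kg_terms
from .preprocess import MaxAbsScaler
from .sgtm import SGTMModel, TransformStep

__all__ = [
    "read_csv_dataset",
    "write_csv_dataset",
    "save_model",
    "load_model",
    "FORMAT_VERSION",
]

FORMAT_VERSION = 1


def read_csv_dataset(path, target_column: str | None = None) -> Dataset:
    """Load a numeric CSV; non-numeric or non-finite cells are rejected
    with their row/column location."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise InvalidInputError(f"{path} contains no data rows")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise InvalidInputError(
                f"non-numeric or missing cell at row {row + 2} (1-based, incl. "
                f"header), column {col!r} in {path}"
            )
        if not np.all(np.isfinite(coerced.to_numpy())):
            row = int(np.flatnonzero(~np.isfinite(coerced.to_numpy()))[0])
            raise InvalidInputError(
                f"non-finite value at row {row + 2}, column {col!r} in {path}"
            )
        df[col] = coerced.astype(float)
    if target_column is None:
        return Dataset(
            X=df.to_numpy(),
            y=None,
            feature_names=tuple(df.columns),
            target_name="__target__",
        )
    if target_column not in df.columns:
        raise InvalidInputError(
            f"target column {target_column!r} not found in {path}; "
            f"available: {list(df.columns)}"
        )
    y = df[target_column].to_numpy()
    feats = df.drop(columns=[target_column])
    return Dataset(
        X=feats.to_numpy(),
        y=y,
        feature_names=tuple(feats.columns),
        target_name=target_column,
    )


def write_csv_dataset(dataset: Dataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")


def _scaler_to_json(s: MaxAbsScaler) -> list:
    return [float(v) for v in s.scale]


def _sgtm_to_json(m: SGTMModel) -> dict:
    return {
        "p": m.p,
        "q": m.q,
        "input_means": m.input_means.tolist(),
        "output_means": m.output_means.tolist(),
        "steps": [
            {
                "step_index": s.step_index,
                "base_direction": s.base_direction.tolist(),
                "alpha": s.alpha,
                "base_row_index": s.base_row_index,
                "base_norm": s.base_norm,
            }
            for s in m.steps
        ],
    }


def _sgtm_from_json(d: dict) -> SGTMModel:
    steps = [
        TransformStep(
            step_index=int(s["step_index"]),
            base_direction=np.asarray(s["base_direction"], dtype=float),
            alpha=float(s["alpha"]),
            base_row_index=int(s["base_row_index"]),
            base_norm=float(s["base_norm"]),
        )
        for s in d["steps"]
    ]
    return SGTMModel(
        steps=steps,
        input_means=np.asarray(d["input_means"], dtype=float),
        output_means=np.asarray(d["output_means"], dtype=float),
        p=int(d["p"]),
        q=int(d["q"]),
    )


def save_model(model: CascadeModel, path) -> None:
    """Serialise a fitted cascade to a self-describing JSON archive."""
    doc = {
        "format_version": FORMAT_VERSION,
        "config": {
            "levels": model.config.levels,
            "degree": model.config.degree,
            "hidden_neurons": model.config.hidden_neurons,
            "seed": model.config.seed,
            "shuffled_partition": model.config.shuffled_partition,
        },
        "feature_names": list(model.feature_names),
        "target_name": model.target_name,
        "levels": [
            {
                "scaler_scale": _scaler_to_json(lvl.scaler),
                "basis_variables": list(lvl.basis.variable_names),
                "basis_degree": lvl.basis.degree,
                "sgtm": _sgtm_to_json(lvl.sgtm),
            }
            for lvl in model.levels
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> CascadeModel:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ArchiveError(f"cannot parse model archive {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format_version") != FORMAT_VERSION:
        raise ArchiveError(
            f"unsupported archive format_version {doc.get('format_version')!r} "
            f"(expected {FORMAT_VERSION})"
        )
    cfg = doc["config"]
    hidden = cfg["hidden_neurons"]
    config = CascadeConfig(
        levels=int(cfg["levels"]),
        degree=int(cfg["degree"]),
        hidden_neurons=hidden if hidden == "full" else int(hidden),
        seed=int(cfg["seed"]),
        shuffled_partition=bool(cfg["shuffled_partition"]),
    )
    levels = []
    for lvl in doc["levels"]:
        basis = kg_terms(lvl["basis_variables"], int(lvl["basis_degree"]))
        levels.append(
            LevelModel(
                scaler=MaxAbsScaler(scale=np.asarray(lvl["scaler_scale"], dtype=float)),
                sgtm=_sgtm_from_json(lvl["sgtm"]),
                basis=basis,
            )
        )
    return CascadeModel(
        config=config,
        levels=levels,
        feature_names=tuple(doc["feature_names"]),
        target_name=str(doc["target_name"]),
    )
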