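"""Random-Forest activity classifiers with out-of-bag mtry tuning.

The forest keeps 500 trees (the standard choice for this kind of activity
recognition work) while ``mtry`` — the number of candidate features sampled
at each split — is tuned by out-of-bag (OOB) error over a small grid.
Tuning probes use a reduced number of trees (``tune_trees``) because the OOB
ranking of mtry values stabilizes long before the full forest is grown; the
winning value is refit with the full tree count.  All randomness flows from
``ModelSpec.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import IntegrityError, UsageError
from .features import feature_columns
from .io_annotation import ACTIVITY_CLASSES

FORMAT_VERSION = 1


def default_mtry_grid(n_features: int) -> list[int]:
    """{floor(sqrt(p)), floor(p/3), floor(p/2)}, deduplicated and sorted."""
    grid = {max(1, int(math.isqrt(n_features))), max(1, n_features // 3), max(1, n_features // 2)}
    return sorted(grid)


@dataclass
class ModelSpec:
    placement: str = "hip"
    feature_set: str = "lag_lead"  # "base" or "lag_lead"
    window_s: float = 10.0
    n_trees: int = 500
    mtry_grid: Sequence[int] | None = None
    seed: int = 0
    tune_trees: int = 100  # trees per OOB tuning probe

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise UsageError("n_trees must be >= 1")
        if self.feature_set not in ("base", "lag_lead"):
            raise UsageError("feature_set must be 'base' or 'lag_lead'")


@dataclass
class TrainedModel:
    spec: ModelSpec
    forest: RandomForestClassifier
    selected_mtry: int
    feature_names: list[str]
    class_order: tuple[str, ...] = ACTIVITY_CLASSES
    oob_errors: dict[int, float] = field(default_factory=dict)


def _check_table(table: pd.DataFrame, feats: list[str]) -> None:
    for col in feats:
        if table[col].isna().any():
            raise IntegrityError(f"feature column {col!r} contains NaN")


def tune_and_fit(table: pd.DataFrame, spec: ModelSpec) -> TrainedModel:
    """Select mtry by OOB error and fit the final forest.

    Ties in OOB error break toward the smaller mtry.  With a singleton grid
    no probes are fit at all.
    """
    feats = feature_columns(table)
    if table["label"].nunique() < 2:
        raise UsageError("training table must contain at least two classes")
    _check_table(table, feats)
    X = table[feats].to_numpy(dtype=float)
    y = table["label"].to_numpy()

    grid = sorted(set(spec.mtry_grid)) if spec.mtry_grid else default_mtry_grid(len(feats))
    if any(m > len(feats) or m < 1 for m in grid):
        raise UsageError(f"mtry grid {grid} incompatible with {len(feats)} features")

    oob_errors: dict[int, float] = {}
    if len(grid) == 1:
        best = grid[0]
    else:
        probe_trees = min(spec.tune_trees, spec.n_trees)
        for mtry in grid:
            probe = RandomForestClassifier(
                n_estimators=probe_trees,
                max_features=mtry,
                oob_score=True,
                random_state=spec.seed % (2**31),
                n_jobs=1,
            )
            probe.fit(X, y)
            oob_errors[mtry] = 1.0 - probe.oob_score_
        best = grid[0]
        for mtry in grid[1:]:
            if oob_errors[mtry] < oob_errors[best]:
                best = mtry

    forest = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=best,
        oob_score=True,
        random_state=spec.seed % (2**31),
        n_jobs=1,
    )
    forest.fit(X, y)
    return TrainedModel(
        spec=spec,
        forest=forest,
        selected_mtry=best,
        feature_names=list(feats),
        oob_errors=oob_errors,
    )


def predict(model: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    """Predict one activity class per row; columns align by name.

    Probability ties among trees break by the fixed activity-class order.
    """
    missing = [c for c in model.feature_names if c not in table.columns]
    if missing:
        raise UsageError(f"table is missing feature column(s) {missing}")
    X = table[model.feature_names].to_numpy(dtype=float)
    proba = model.forest.predict_proba(X)
    classes = list(model.forest.classes_)
    ordered = np.zeros((X.shape[0], len(model.class_order)))
    for j, cls in enumerate(model.class_order):
        if cls in classes:
            ordered[:, j] = proba[:, classes.index(cls)]
    winners = ordered.argmax(axis=1)  # first max -> class_order tie-break
    return np.asarray(model.class_order)[winners]


def save_model(model: TrainedModel, path) -> None:
    joblib.dump(
        {
            "format_version": FORMAT_VERSION,
            "spec": model.spec,
            "forest": model.forest,
            "selected_mtry": model.selected_mtry,
            "feature_names": model.feature_names,
            "class_order": model.class_order,
            "oob_errors": model.oob_errors,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    blob = joblib.load(path)
    if blob.get("format_version") != FORMAT_VERSION:
        raise IntegrityError("unsupported model archive version")
    return TrainedModel(
        spec=blob["spec"],
        forest=blob["forest"],
        selected_mtry=blob["selected_mtry"],
        feature_names=blob["feature_names"],
        class_order=blob["class_order"],
        oob_errors=blob["oob_errors"],
    )


def fold_spec(spec: ModelSpec, fold_index: int) -> ModelSpec:
    """Per-fold spec with a deterministically derived seed (< 2^31)."""
    return replace(spec, seed=(spec.seed * 1_000_003 + fold_index + 1) % (2**31))
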