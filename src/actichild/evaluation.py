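"""Leave-one-subject-out evaluation, F-scores, confusion matrices, kappa.

Confusion matrices follow the orientation used throughout this package's
reports: rows are predictions, columns are observations, in the fixed
activity-class order.  Metrics are computed on predictions pooled across all
LOSO folds; per-subject summaries are emitted alongside for transparency.
The weighted average F-score weights each class by its observed support, so
classes absent from the test data contribute nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import UsageError
from .io_annotation import ACTIVITY_CLASSES
from .modeling import ModelSpec, fold_spec, predict, tune_and_fit

logger = logging.getLogger(__name__)


def confusion_matrix(observed, predicted) -> np.ndarray:
    """5x5 count matrix, rows = predicted, columns = observed."""
    return _sk_confusion(observed, predicted, labels=list(ACTIVITY_CLASSES)).T


def f_scores(cm: np.ndarray) -> tuple[pd.DataFrame, float]:
    """Per-class precision/recall/F and the support-weighted average F.

    Zero-denominator precision, recall or F are set to 0; classes with zero
    observed support carry zero weight in the average.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise UsageError("empty confusion matrix")
    tp = np.diag(cm).astype(float)
    pred_tot = cm.sum(axis=1).astype(float)  # row sums: predicted
    obs_tot = cm.sum(axis=0).astype(float)  # column sums: observed support
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        recall = np.where(obs_tot > 0, tp / obs_tot, 0.0)
        pr = precision + recall
        f = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    weighted = float((obs_tot * f).sum() / obs_tot.sum())
    per_class = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f_score": f,
            "support": obs_tot.astype(int),
        },
        index=list(ACTIVITY_CLASSES),
    )
    return per_class, weighted


def cohens_kappa(coder1, coder2) -> float:
    """Unweighted Cohen's kappa between two coders' label sequences."""
    a = np.asarray(coder1)
    b = np.asarray(coder2)
    if a.shape != b.shape or a.size < 1:
        raise UsageError("coder sequences must be equal-length and non-empty")
    n = a.size
    p_o = float((a == b).mean())
    codes = np.union1d(a, b)
    p_e = sum(float((a == c).mean()) * float((b == c).mean()) for c in codes)
    if p_e >= 1.0:
        raise UsageError("chance agreement is 1; kappa is undefined")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class EvaluationReport:
    spec: ModelSpec
    predictions: pd.DataFrame  # subject_id, window_index, observed, predicted, mixed
    cm: np.ndarray
    per_class: pd.DataFrame
    weighted_f: float
    mixed_fraction: float
    per_subject: pd.DataFrame  # subject_id, n_windows, weighted_f
    folds: list[dict] | None = None  # test_subject, train_subjects per fold


def loso_evaluate(table: pd.DataFrame, spec: ModelSpec) -> EvaluationReport:
    """Leave-one-subject-out cross-validation on a pooled feature table.

    One fold per subject; the held-out subject never contributes to that
    fold's training data.  Predictions are pooled before computing metrics.
    """
    subjects = sorted(table["subject_id"].unique())
    if len(subjects) < 2:
        raise UsageError("LOSO needs at least two subjects")
    frames = []
    folds = []
    for k, sid in enumerate(subjects):
        test = table[table["subject_id"] == sid]
        train = table[table["subject_id"] != sid]
        if len(test) == 0:
            logger.warning("subject %s has no labeled windows; skipped", sid)
            continue
        folds.append(
            {
                "test_subject": sid,
                "train_subjects": sorted(train["subject_id"].unique()),
                "n_train": len(train),
                "n_test": len(test),
            }
        )
        model = tune_and_fit(train, fold_spec(spec, k))
        pred = predict(model, test)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "window_index": test["window_index"].to_numpy(),
                    "observed": test["label"].to_numpy(),
                    "predicted": pred,
                    "mixed": test["mixed"].to_numpy(),
                }
            )
        )
    pooled = pd.concat(frames, ignore_index=True)
    cm = confusion_matrix(pooled["observed"], pooled["predicted"])
    per_class, weighted = f_scores(cm)
    per_subject = (
        pooled.groupby("subject_id")
        .apply(
            lambda g: pd.Series(
                {
                    "n_windows": len(g),
                    "weighted_f": f_scores(confusion_matrix(g["observed"], g["predicted"]))[1],
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return EvaluationReport(
        spec=spec,
        predictions=pooled,
        cm=cm,
        per_class=per_class,
        weighted_f=weighted,
        mixed_fraction=float(pooled["mixed"].mean()),
        per_subject=per_subject,
        folds=folds,
    )


def report_render(report: EvaluationReport, out_dir, stem: str, heatmap: bool = False) -> dict:
    """Write the metrics table and the column-normalized confusion matrix.

    The matrix file holds percentages per observed class (columns sum to
    100); observed-empty classes render as zeros and are flagged in a
    trailing comment line.  Returns the written paths.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    metrics_path = os.path.join(out_dir, f"{stem}_metrics.csv")
    matrix_path = os.path.join(out_dir, f"{stem}_confusion_pct.csv")

    meta = report.per_class.copy()
    meta.index.name = "class"
    with open(metrics_path, "w") as fh:
        fh.write(f"# placement={report.spec.placement} feature_set={report.spec.feature_set} "
                 f"window_s={report.spec.window_s} n_trees={report.spec.n_trees} "
                 f"seed={report.spec.seed}\n")
        fh.write(f"# weighted_f={report.weighted_f:.6f} mixed_fraction={report.mixed_fraction:.6f}\n")
        meta.to_csv(fh)

    cm = report.cm.astype(float)
    col = cm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(col > 0, 100.0 * cm / np.where(col > 0, col, 1.0), 0.0)
    mat = pd.DataFrame(pct, index=list(ACTIVITY_CLASSES), columns=list(ACTIVITY_CLASSES))
    mat.index.name = "predicted\\observed"
    with open(matrix_path, "w") as fh:
        mat.round(1).to_csv(fh)
        empty = [c for c, s in zip(ACTIVITY_CLASSES, col) if s == 0]
        if empty:
            fh.write(f"# zero observed support: {','.join(empty)}\n")

    paths = {"metrics": metrics_path, "matrix": matrix_path}
    if heatmap:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4.5, 4))
        im = ax.imshow(pct, cmap="Blues", vmin=0, vmax=100)
        ax.set_xticks(range(5), ACTIVITY_CLASSES, rotation=45, ha="right")
        ax.set_yticks(range(5), ACTIVITY_CLASSES)
        ax.set_xlabel("observed")
        ax.set_ylabel("predicted")
        for i in range(5):
            for j in range(5):
                ax.text(j, i, f"{pct[i, j]:.0f}", ha="center", va="center", fontsize=8)
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        png = os.path.join(out_dir, f"{stem}_confusion.png")
        fig.savefig(png, dpi=120)
        plt.close(fig)
        paths["heatmap"] = png
    return paths
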