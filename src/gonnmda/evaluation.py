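"""Cross-validation orchestration and metrics.

AUC is the probability that a random positive outranks a random negative
(trapezoidal ROC, midrank ties); AUPR integrates the precision-recall
curve.  Thresholded metrics (accuracy, precision, recall, F1) binarize
scores at 0.5; ratios with zero denominators are reported as 0 and
flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

METRIC_NAMES = ("auc", "aupr", "accuracy", "precision", "recall", "f1")


@dataclass
class FoldResult:
    fold_id: int
    y_true: np.ndarray
    y_score: np.ndarray
    metrics: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.y_true = np.asarray(self.y_true, dtype=float)
        self.y_score = np.asarray(self.y_score, dtype=float)
        if self.y_true.shape != self.y_score.shape:
            raise ValueError("y_true and y_score lengths differ")
        if not self.metrics:
            self.metrics = compute_all_metrics(self.y_true, self.y_score)


def kfold_split(
    n_samples_or_labels, k: int, seed: int
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Stratified, shuffled, label-balanced k-fold index split."""
    y = np.asarray(n_samples_or_labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(y) < k:
        raise ValueError(f"cannot split {len(y)} samples into {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def confusion_metrics(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> Dict[str, float]:
    """Accuracy, precision, recall, F1 from binary predictions.

    Accuracy is (TP+TN)/total; undefined ratios are reported as 0 with a
    ``*_undefined`` flag in the result.
    """
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("length mismatch")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValueError("inputs must be binary")
    tp = int(((yt == 1) & (yp == 1)).sum())
    tn = int(((yt == 0) & (yp == 0)).sum())
    fp = int(((yt == 0) & (yp == 1)).sum())
    fn = int(((yt == 1) & (yp == 0)).sum())
    out: Dict[str, float] = {
        "accuracy": (tp + tn) / max(tp + tn + fp + fn, 1),
    }
    if tp + fp == 0:
        out["precision"], out["precision_undefined"] = 0.0, True
    else:
        out["precision"] = tp / (tp + fp)
    if tp + fn == 0:
        out["recall"], out["recall_undefined"] = 0.0, True
    else:
        out["recall"] = tp / (tp + fn)
    p, r = out["precision"], out["recall"]
    if p + r == 0:
        out["f1"], out["f1_undefined"] = 0.0, True
    else:
        out["f1"] = 2 * p * r / (p + r)
    return out


def threshold_free_metrics(
    y_true: Sequence[int], y_score: Sequence[float]
) -> Tuple[float, float]:
    """(AUC, AUPR); both classes must be present."""
    yt = np.asarray(y_true, dtype=int)
    ys = np.asarray(y_score, dtype=float)
    if yt.min() == yt.max():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(yt, ys)), float(average_precision_score(yt, ys))


def compute_all_metrics(
    y_true: np.ndarray, y_score: np.ndarray, threshold: float = 0.5
) -> Dict[str, float]:
    auc, aupr = threshold_free_metrics(y_true, y_score)
    conf = confusion_metrics(
        np.asarray(y_true, dtype=int), (np.asarray(y_score) >= threshold).astype(int)
    )
    return {
        "auc": auc,
        "aupr": aupr,
        "accuracy": conf["accuracy"],
        "precision": conf["precision"],
        "recall": conf["recall"],
        "f1": conf["f1"],
    }


def summarize(folds: Sequence[FoldResult]) -> Dict[str, Dict[str, float]]:
    """Mean and standard deviation of each metric over folds."""
    out: Dict[str, Dict[str, float]] = {}
    for name in METRIC_NAMES:
        vals = np.array([f.metrics[name] for f in folds])
        out[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
    return out


def run_cv(
    labels: Sequence[int],
    k: int,
    fold_runner: Callable[[int, np.ndarray, np.ndarray], Tuple[np.ndarray, np.ndarray]],
    seed: int,
) -> Tuple[List[FoldResult], Dict[str, Dict[str, float]]]:
    """k-fold cross-validation loop.

    ``fold_runner(fold_id, train_idx, test_idx)`` trains on the training
    indices only (leakage hygiene is its responsibility) and returns
    (y_true, y_score) for the test indices.
    """
    folds: List[FoldResult] = []
    for fold_id, (tr, te) in enumerate(kfold_split(labels, k, seed)):
        try:
            y_true, y_score = fold_runner(fold_id, tr, te)
        except Exception as e:
            raise RuntimeError(f"fold {fold_id} failed: {e}") from e
        folds.append(FoldResult(fold_id, y_true, y_score))
    return folds, summarize(folds)
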