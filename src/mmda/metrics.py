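"""Screening metrics: confusion counts, accuracy, sensitivity, ROC/AUC,
and feature-embedding export for external visualization."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DomainDataset
from .errors import ShapeError, UndefinedMetricError


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Binary confusion counts; positive class = referable (1)."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ShapeError(f"pred {pred.shape} vs truth {truth.shape}")
    return ConfusionCounts(
        tp=int(((pred == 1) & (truth == 1)).sum()),
        tn=int(((pred == 0) & (truth == 0)).sum()),
        fp=int(((pred == 1) & (truth == 0)).sum()),
        fn=int(((pred == 0) & (truth == 1)).sum()),
    )


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined with zero samples")
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined with no positive samples")
    return c.tp / (c.tp + c.fn)


def roc(scores: np.ndarray, truth: np.ndarray) -> RocCurve:
    """ROC by threshold sweep; thresholds at midpoints between consecutive
    unique scores plus +/-inf endpoints; AUC by the trapezoid rule."""
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth, dtype=int)
    if scores.shape != truth.shape:
        raise ShapeError(f"scores {scores.shape} vs truth {truth.shape}")
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC needs at least one positive and one negative")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([np.inf], mids[::-1], [-np.inf]))
    fpr = np.empty(len(thresholds))
    tpr = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = scores >= t
        tpr[i] = (pred & (truth == 1)).sum() / n_pos
        fpr[i] = (pred & (truth == 0)).sum() / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def referable_scores(probs: np.ndarray) -> np.ndarray:
    """Positive-class score: column 1 for K=2, summed mass on grades >=2 for K=5."""
    probs = np.asarray(probs)
    if probs.shape[1] == 2:
        return probs[:, 1]
    return probs[:, 2:].sum(axis=1)


def evaluate_binary(probs: np.ndarray, truth: np.ndarray) -> dict:
    """All screening metrics from output probabilities + binary truth."""
    scores = referable_scores(probs)
    pred = (scores >= 0.5).astype(int)
    c = confusion(pred, truth)
    curve = roc(scores, truth)
    return {
        "accuracy": accuracy(c),
        "sensitivity": sensitivity(c),
        "auc": curve.auc,
        "confusion": {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn},
    }


def export_embeddings(model, data: DomainDataset, out_path: str | Path) -> pd.DataFrame:
    """Write (id, label, d feature columns) for downstream t-SNE/plotting."""
    feats = model.features(data.X)
    df = pd.DataFrame(feats, columns=[f"f{i}" for i in range(feats.shape[1])])
    df.insert(0, "id", data.ids)
    df.insert(1, "label", data.y if data.y is not None else "")
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_path, index=False)
    return df
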